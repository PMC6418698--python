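import pytest

from dicerclass.fixtures import load_published_cohort, packaged_transcript
from dicerclass.transcript import TranscriptModel


def make_toy(exons, strand="+", utr5=0, cds_len=None):
    """Build a toy transcript by walking the spliced sequence directly.

    The CDS genomic bounds are derived by an arithmetic walk that is
    independent of TranscriptModel's own coordinate mapping, so toys can
    serve as oracles for it.
    """
    order = list(exons) if strand == "+" else list(exons)[::-1]
    spliced = []  # genomic positions in transcript (5'->3') order
    for s, e in order:
        rng = range(s, e) if strand == "+" else range(e - 1, s - 1, -1)
        spliced.extend(rng)
    total = len(spliced)
    if cds_len is None:
        cds_len = ((total - utr5) // 3) * 3
    cds_positions = spliced[utr5: utr5 + cds_len]
    lo, hi = min(cds_positions), max(cds_positions)
    return TranscriptModel(
        transcript_id="TOY",
        chromosome="chrT",
        strand=strand,
        exons=tuple(exons),
        cds_start=lo,
        cds_end=hi + 1,
    ), spliced, cds_positions


@pytest.fixture(scope="session")
def model():
    return packaged_transcript()


@pytest.fixture(scope="session")
def tcga():
    return load_published_cohort("tcga")


@pytest.fixture(scope="session")
def target():
    return load_published_cohort("target")
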