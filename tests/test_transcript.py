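"""Transcript geometry: loading, splice binning, codon mapping, hotspots."""

import pytest
from hypothesis import given, settings, strategies as st

from dicerclass.transcript import (
    DICER1_HOTSPOTS,
    SpliceRegion,
    SpliceSide,
    TranscriptError,
    TranscriptModel,
    codon_of,
    is_hotspot,
    load_transcript,
    splice_context,
)

from conftest import make_toy


def brute_force_context(position, model):
    """Independent oracle: exhaustive distance to every exon edge."""
    for s, e in model.exons:
        if s <= position < e:
            return ("exonic", 0)
    if position < model.tx_start or position >= model.tx_end:
        return ("deep_intronic", None)
    best = None
    for s, e in model.exons:
        if position < s:
            best = min(best, s - position) if best else s - position
        elif position >= e:
            d = position - e + 1
            best = min(best, d) if best else d
    if best <= 2:
        return ("canonical_splice", best)
    if best <= 9:
        return ("splice_region", best)
    return ("deep_intronic", best)


class TestLoading:
    def test_packaged_transcript_invariants(self, model):
        assert model.transcript_id == "NM_177438.2"
        assert model.strand == "-"
        assert len(model.exons) == 27
        assert model.cds_length % 3 == 0
        assert model.cds_length == 3 * (model.protein_length + 1)
        assert model.protein_length == 1922

    def test_toy_protein_length(self):
        # 2 exons, 9 coding bases -> 2 residues plus the stop codon
        toy, _, _ = make_toy([(10, 15), (20, 24)], strand="+", cds_len=9)
        assert toy.protein_length == 2

    def test_overlapping_exons_rejected(self):
        with pytest.raises(TranscriptError):
            TranscriptModel("X", "chr1", "+", ((10, 20), (15, 30)), 10, 28)

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(TranscriptError):
            TranscriptModel("X", "chr1", "+", ((10, 20),), 10, 18)

    def test_load_rejects_multi_record_files(self, tmp_path, model):
        line = "\t".join(
            ["T", "chr1", "+", "10", "20", "10", "19", "1", "10,", "20,"]
        )
        p = tmp_path / "two.genepred"
        p.write_text(line + "\n" + line + "\n")
        with pytest.raises(TranscriptError):
            load_transcript(p)


class TestSpliceContext:
    def test_first_intronic_base_is_donor_plus_one(self):
        toy, _, _ = make_toy([(100, 110), (120, 132), (150, 159)], "+", cds_len=30)
        ctx = splice_context(110, toy)
        assert (ctx.region, ctx.intronic_distance, ctx.side) == (
            SpliceRegion.CANONICAL_SPLICE, 1, SpliceSide.DONOR,
        )

    def test_donor_side_follows_strand(self):
        toy, _, _ = make_toy([(100, 110), (120, 132), (150, 159)], "-", cds_len=30)
        # on the minus strand the genomic-left exon end is an acceptor side
        assert splice_context(110, toy).side == SpliceSide.ACCEPTOR
        assert splice_context(119, toy).side == SpliceSide.DONOR

    def test_c4206_plus_one_is_canonical_donor(self, model):
        g = model.genomic_of_c(4206, 1)
        ctx = splice_context(g, model)
        assert ctx.region == SpliceRegion.CANONICAL_SPLICE
        assert ctx.intronic_distance == 1
        assert ctx.side == SpliceSide.DONOR

    def test_distance_five_is_splice_region(self, model):
        g = model.genomic_of_c(4206, 5)
        ctx = splice_context(g, model)
        assert (ctx.region, ctx.intronic_distance) == (SpliceRegion.SPLICE_REGION, 5)

    def test_exonic_base(self, model):
        g = model.genomic_of_c(100)
        assert splice_context(g, model) == splice_context(g, model)
        assert splice_context(g, model).region == SpliceRegion.EXONIC
        assert splice_context(g, model).intronic_distance == 0

    def test_distance_twelve_is_deep_intronic(self, model):
        g = model.genomic_of_c(4206, 12)
        assert splice_context(g, model).region == SpliceRegion.DEEP_INTRONIC

    def test_outside_span_reports_deep_intronic_with_floored_distance(self, model):
        ctx = splice_context(model.tx_start - 3, model)
        assert ctx.region == SpliceRegion.DEEP_INTRONIC
        assert ctx.intronic_distance >= 10

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_scan_matches_brute_force(self, strand):
        """Region bins partition every base and agree with the oracle."""
        toy, _, _ = make_toy(
            [(100, 113), (125, 140), (170, 185), (210, 222)], strand, utr5=2, cds_len=36
        )
        for pos in range(toy.tx_start - 15, toy.tx_end + 15):
            expect_region, expect_dist = brute_force_context(pos, toy)
            ctx = splice_context(pos, toy)
            assert ctx.region.value == expect_region, pos
            if expect_dist is not None:
                assert ctx.intronic_distance == expect_dist, pos
            # side is only defined for intronic positions inside the span
            if ctx.region == SpliceRegion.EXONIC:
                assert ctx.side == SpliceSide.NONE


class TestCodonMapping:
    def test_first_and_last_cds_bases(self):
        toy, _, cds = make_toy([(100, 110), (120, 132), (150, 159)], "+", utr5=2, cds_len=27)
        assert codon_of(cds[0], toy) == 1
        L = toy.protein_length
        # last base before the stop codon maps to residue L
        assert codon_of(cds[3 * L - 1], toy) == L

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_cds_base_matches_spliced_walk(self, strand):
        """codon_of agrees with direct enumeration of the spliced CDS."""
        toy, _, cds = make_toy(
            [(100, 111), (125, 140), (170, 182)], strand, utr5=4, cds_len=30
        )
        for i, pos in enumerate(cds):
            assert codon_of(pos, toy) == i // 3 + 1

    def test_non_cds_positions_return_none(self):
        toy, spliced, cds = make_toy([(100, 110), (120, 132)], "+", utr5=3, cds_len=15)
        utr_positions = [p for p in spliced if p not in set(cds)]
        assert utr_positions
        for pos in utr_positions:
            assert codon_of(pos, toy) is None
        assert codon_of(115, toy) is None  # intronic

    def test_c_to_genomic_round_trip(self, model):
        for c in (1, 100, 2710, 4206, 5428, model.cds_length):
            g = model.genomic_of_c(c)
            assert model.c_of_genomic(g) == c

    @settings(derandomize=True, max_examples=60)
    @given(
        strand=st.sampled_from(["+", "-"]),
        sizes=st.lists(st.integers(4, 30), min_size=2, max_size=6),
        gaps=st.lists(st.integers(3, 40), min_size=5, max_size=5),
        utr5=st.integers(0, 3),
    )
    def test_codon_identity_on_random_toys(self, strand, sizes, gaps, utr5):
        exons, pos = [], 100
        for size, gap in zip(sizes, gaps):
            exons.append((pos, pos + size))
            pos += size + gap
        total = sum(e - s for s, e in exons)
        cds_len = ((total - utr5) // 3) * 3
        if cds_len < 6:
            return
        toy, _, cds = make_toy(exons, strand, utr5=utr5, cds_len=cds_len)
        # inverse mapping composed with codon_of is the identity
        for c in range(1, cds_len + 1):
            g = toy.genomic_of_c(c)
            assert g == cds[c - 1]
            assert codon_of(g, toy) == (c - 1) // 3 + 1


class TestHotspots:
    @pytest.mark.parametrize(
        "residue,expected", [(1705, True), (1709, True), (1809, True), (1810, True),
                             (1813, True), (1578, False), (1, False)]
    )
    def test_registry_membership(self, residue, expected):
        assert is_hotspot(residue, DICER1_HOTSPOTS) is expected

    def test_membership_ignores_alternate_amino_acid(self):
        # matching is on the residue index; any substitution there qualifies
        assert is_hotspot(1810)
        assert 1810 in DICER1_HOTSPOTS

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            is_hotspot(0)
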