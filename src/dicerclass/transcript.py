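"""Transcript coordinate geometry for a single canonical transcript.

Everything downstream of variant classification that involves *where* a
variant sits — exon vs intron, distance to the nearest splice junction,
which protein residue a coding base belongs to — is answered here.  The
engine is strand-generic: the canonical DICER1 transcript (NM_177438.2)
lies on the minus strand of chromosome 14, but all the arithmetic is done
in strand-normalised transcript coordinates so that plus-strand toy
transcripts exercise the same code paths in tests.

Conventions
-----------
* Internal genomic coordinates are 0-based, half-open intervals.
* User-facing positions (VCF, HGVS) are 1-based; converters at the module
  boundary do the shift.
* "Intronic distance" counts intronic bases only: the first base of an
  intron is at distance 1, exonic bases are at distance 0.  Distances 1-2
  are the canonical splice site, 3-9 the splice region, >=10 deep intronic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "TranscriptModel",
    "TranscriptError",
    "SpliceContext",
    "SpliceRegion",
    "SpliceSide",
    "HotspotRegistry",
    "DICER1_HOTSPOTS",
    "load_transcript",
    "splice_context",
    "codon_of",
    "is_hotspot",
    "CANONICAL_SPLICE_MAX",
    "SPLICE_REGION_MAX",
    "DEEP_INTRONIC_MIN",
]

#: Intronic distance thresholds.  1-2 bp from the junction is the canonical
#: splice site; up to 9 bp is the splice region; 10 bp or more is deep
#: intronic and out of analysis scope.
CANONICAL_SPLICE_MAX = 2
SPLICE_REGION_MAX = 9
DEEP_INTRONIC_MIN = 10


class TranscriptError(ValueError):
    """Raised for malformed or internally inconsistent transcript records."""


class SpliceRegion(str, enum.Enum):
    EXONIC = "exonic"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    DEEP_INTRONIC = "deep_intronic"


class SpliceSide(str, enum.Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    NONE = "none"


@dataclass(frozen=True)
class SpliceContext:
    """Where a genomic position sits relative to the exon/intron structure.

    ``intronic_distance`` is 0 for exonic positions and the 1-based count of
    intronic bases from the nearest junction otherwise.  ``side`` reports
    whether the nearest junction is a donor (transcriptional 3' end of an
    exon) or acceptor site; exonic positions carry ``none``.
    """

    region: SpliceRegion
    intronic_distance: int
    side: SpliceSide


@dataclass(frozen=True)
class HotspotRegistry:
    """Immutable registry of hotspot protein residues.

    Membership is decided on the residue index alone: any missense change at
    a registered codon counts, whatever the alternate amino acid.  The
    reference amino acid is carried for documentation and HGVS rendering.
    """

    entries: frozenset[tuple[int, str]]

    def __contains__(self, residue_index: int) -> bool:
        return any(idx == residue_index for idx, _ in self.entries)

    def residues(self) -> frozenset[int]:
        return frozenset(idx for idx, _ in self.entries)


#: The five RNase IIIb metal-binding residues of DICER1 where missense
#: variation abolishes miRNA-processing activity.
DICER1_HOTSPOTS = HotspotRegistry(
    entries=frozenset({(1705, "E"), (1709, "D"), (1809, "G"), (1810, "D"), (1813, "E")})
)


@dataclass(frozen=True)
class TranscriptModel:
    """Single-transcript exon/CDS model with coordinate mapping.

    Parameters
    ----------
    transcript_id : accession, e.g. ``"NM_177438.2"``.
    chromosome : chromosome name as used by the variant files.
    strand : ``"+"`` or ``"-"``.
    exons : genomic exon intervals, 0-based half-open, ascending, disjoint.
    cds_start, cds_end : genomic bounds of the coding sequence (half-open),
        stop codon included.
    """

    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    # caches, derived in __post_init__
    _tx_len: int = field(init=False, repr=False, compare=False, default=0)
    _cds_len: int = field(init=False, repr=False, compare=False, default=0)
    _cds_tx_start: int = field(init=False, repr=False, compare=False, default=0)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise TranscriptError("transcript has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise TranscriptError(f"empty or inverted exon interval ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                # introns must be >= 1 bp, so adjacency is also an error
                raise TranscriptError(
                    f"exons overlap or are adjacent at genomic position {start}"
                )
            prev_end = end
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise TranscriptError("CDS bounds fall outside the transcript span")
        for bound in (self.cds_start, self.cds_end - 1):
            if self._exon_index(bound) is None:
                raise TranscriptError(f"CDS bound {bound} is not exonic")
        cds_len = sum(
            max(0, min(end, self.cds_end) - max(start, self.cds_start))
            for start, end in self.exons
        )
        if cds_len % 3 != 0:
            raise TranscriptError(f"CDS length {cds_len} is not a multiple of 3")
        object.__setattr__(self, "_cds_len", cds_len)
        object.__setattr__(self, "_tx_len", sum(e - s for s, e in self.exons))
        first_cds_genomic = self.cds_start if self.strand == "+" else self.cds_end - 1
        object.__setattr__(self, "_cds_tx_start", self.tx_offset(first_cds_genomic))

    # -- span ------------------------------------------------------------
    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return self._cds_len

    @property
    def protein_length(self) -> int:
        """Number of residues encoded, excluding the stop codon."""
        return self._cds_len // 3 - 1

    # -- coordinate mapping ---------------------------------------------
    def _exon_index(self, position: int) -> Optional[int]:
        for i, (start, end) in enumerate(self.exons):
            if start <= position < end:
                return i
        return None

    def is_exonic(self, position: int) -> bool:
        return self._exon_index(position) is not None

    def tx_offset(self, position: int) -> Optional[int]:
        """0-based offset of a genomic position along the spliced transcript.

        Counts from the transcriptional 5' end (highest genomic coordinate
        for minus-strand transcripts).  Returns None for intronic positions.
        """
        idx = self._exon_index(position)
        if idx is None:
            return None
        upstream = sum(e - s for s, e in self.exons[:idx])
        within = position - self.exons[idx][0]
        offset_plus = upstream + within
        if self.strand == "+":
            return offset_plus
        return self._tx_len - 1 - offset_plus

    def genomic_of_tx(self, offset: int) -> int:
        """Inverse of :meth:`tx_offset`."""
        if not 0 <= offset < self._tx_len:
            raise TranscriptError(f"transcript offset {offset} out of range")
        offset_plus = offset if self.strand == "+" else self._tx_len - 1 - offset
        for start, end in self.exons:
            size = end - start
            if offset_plus < size:
                return start + offset_plus
            offset_plus -= size
        raise AssertionError("unreachable")

    def cds_offset(self, position: int) -> Optional[int]:
        """0-based offset within the CDS (stop codon included), or None."""
        tx = self.tx_offset(position)
        if tx is None:
            return None
        off = tx - self._cds_tx_start
        if 0 <= off < self._cds_len:
            return off
        return None

    def is_utr(self, position: int) -> bool:
        """True for exonic positions outside the CDS."""
        return self.is_exonic(position) and self.cds_offset(position) is None

    def genomic_of_c(self, c_position: int, intronic_offset: int = 0) -> int:
        """Genomic (0-based) position of an HGVS c. coordinate.

        ``c_position`` is 1-based within the CDS; a non-zero
        ``intronic_offset`` walks into the adjoining intron in transcript
        direction (``+k`` downstream of the exonic base, ``-k`` upstream),
        matching HGVS ``c.X+k`` / ``c.X-k`` notation.
        """
        if not 1 <= c_position <= self._cds_len:
            raise TranscriptError(f"c. position {c_position} outside CDS 1..{self._cds_len}")
        g = self.genomic_of_tx(self._cds_tx_start + c_position - 1)
        if intronic_offset == 0:
            return g
        step = intronic_offset if self.strand == "+" else -intronic_offset
        return g + step

    def c_of_genomic(self, position: int) -> Optional[int]:
        """1-based HGVS c. coordinate of an exonic CDS base, or None."""
        off = self.cds_offset(position)
        return None if off is None else off + 1

    # -- junctions --------------------------------------------------------
    def junctions(self) -> Iterable[tuple[int, SpliceSide]]:
        """Yield (genomic boundary base adjacent to the intron, side).

        For each intron the two flanking exon-edge coordinates are reported:
        the edge at the transcriptional 3' end of the upstream exon is the
        donor, the edge at the 5' start of the downstream exon the acceptor.
        """
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            # boundary between exon ending at e1 (exclusive) and exon at s2
            if self.strand == "+":
                yield e1 - 1, SpliceSide.DONOR
                yield s2, SpliceSide.ACCEPTOR
            else:
                yield e1 - 1, SpliceSide.ACCEPTOR
                yield s2, SpliceSide.DONOR


def splice_context(position: int, model: TranscriptModel) -> SpliceContext:
    """Bin a genomic position into the exon/splice geometry classes.

    Exonic bases are (exonic, 0, none).  Intronic bases report the count of
    intronic bases to the nearest junction and whether that junction is a
    donor or acceptor.  Positions outside the transcript span are reported
    as deep intronic with the distance floored at the deep-intronic
    threshold (they carry no junction side).
    """
    if model.is_exonic(position):
        return SpliceContext(SpliceRegion.EXONIC, 0, SpliceSide.NONE)

    if position < model.tx_start or position >= model.tx_end:
        dist = max(
            DEEP_INTRONIC_MIN,
            (model.tx_start - position) if position < model.tx_start else (position - model.tx_end + 1),
        )
        return SpliceContext(SpliceRegion.DEEP_INTRONIC, dist, SpliceSide.NONE)

    best_dist: Optional[int] = None
    best_side = SpliceSide.NONE
    for edge, side in model.junctions():
        # number of intronic bases between `position` and this exon edge
        dist = abs(position - edge)
        if best_dist is None or dist < best_dist or (
            dist == best_dist and side == SpliceSide.DONOR
        ):
            # tie (mid-intron, even length): donor wins deterministically
            best_dist, best_side = dist, side
    assert best_dist is not None and best_dist >= 1
    if best_dist <= CANONICAL_SPLICE_MAX:
        region = SpliceRegion.CANONICAL_SPLICE
    elif best_dist <= SPLICE_REGION_MAX:
        region = SpliceRegion.SPLICE_REGION
    else:
        region = SpliceRegion.DEEP_INTRONIC
    return SpliceContext(region, best_dist, best_side)


def codon_of(position: int, model: TranscriptModel) -> Optional[int]:
    """1-based codon (residue) index of an exonic CDS base, or None.

    The stop codon is numbered ``protein_length + 1``; positions in UTRs or
    introns return None.
    """
    off = model.cds_offset(position)
    return None if off is None else off // 3 + 1


def is_hotspot(residue_index: int, registry: HotspotRegistry = DICER1_HOTSPOTS) -> bool:
    """True iff the residue index is a registered hotspot codon."""
    if residue_index < 1:
        raise ValueError("residue index must be >= 1")
    return residue_index in registry


# ---------------------------------------------------------------------------
# loading


def _parse_genepred_line(line: str) -> TranscriptModel:
    fields = line.rstrip("\n").split("\t")
    # tolerate the UCSC "bin" column variant
    if len(fields) >= 11 and fields[0].isdigit() and fields[2] in ("+", "-"):
        fields = fields[1:]
    if len(fields) < 10:
        raise TranscriptError(
            f"genePred record has {len(fields)} fields, expected at least 10"
        )
    name, chrom, strand, tx_start, tx_end, cds_start, cds_end, exon_count = fields[:8]
    starts, ends = fields[8], fields[9]
    try:
        exon_starts = [int(x) for x in starts.rstrip(",").split(",")]
        exon_ends = [int(x) for x in ends.rstrip(",").split(",")]
    except ValueError as exc:
        raise TranscriptError(f"malformed exon coordinate list: {exc}") from exc
    if len(exon_starts) != len(exon_ends) or len(exon_starts) != int(exon_count):
        raise TranscriptError("exonStarts/exonEnds/exonCount disagree")
    exons = tuple(zip(exon_starts, exon_ends))
    model = TranscriptModel(
        transcript_id=name,
        chromosome=chrom,
        strand=strand,
        exons=exons,
        cds_start=int(cds_start),
        cds_end=int(cds_end),
    )
    if (int(tx_start), int(tx_end)) != (model.tx_start, model.tx_end):
        raise TranscriptError("txStart/txEnd disagree with the exon list")
    return model


def load_transcript(path: str | Path) -> TranscriptModel:
    """Load a single transcript from a genePred-dialect text file.

    The file must contain exactly one non-comment record with the UCSC
    genePred columns (name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds); a leading numeric ``bin``
    column is tolerated.  All model invariants are validated on load.
    """
    path = Path(path)
    records = [
        line
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(records) != 1:
        raise TranscriptError(
            f"{path} contains {len(records)} transcript records, expected exactly 1"
        )
    return _parse_genepred_line(records[0])
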