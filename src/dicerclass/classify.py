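"""Four-bin germline pathogenicity rule engine and two-rule somatic rule.

Germline variants on the canonical DICER1 transcript are binned into
P (pathogenic), LP (likely pathogenic), VUS (uncertain significance) and
LB (likely benign).  The P rules are score-free: loss-of-function
(nonsense/frameshift), canonical-splice-site position (1-2 intronic bp
from a junction), missense at an RNase IIIb hotspot codon, or an exact
match in a user-supplied knowledge base of variants credibly reported
pathogenic.  A non-hotspot missense variant is LP when it clears the
in-silico criterion in force: metaSVM category "Deleterious", scaled CADD
strictly > 30, REVEL strictly > 0.75, or any of the three.  Splice-region
variants (3-9 intronic bp), in-frame deletions, and missense variants
whose relevant scores are all missing are VUS; synonymous and
sub-threshold missense variants are LB.

Somatic calls use the shorter published convention: loss-of-function
(canonical-splice included) or hotspot missense is pathogenic, everything
else is not.

Rules are evaluated in a fixed priority order; the result records every
P rule that fired so classifications are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .hgvs import parse_hgvs_c, parse_hgvs_p
from .transcript import (
    CANONICAL_SPLICE_MAX,
    DICER1_HOTSPOTS,
    HotspotRegistry,
    SpliceRegion,
    TranscriptModel,
    codon_of,
    is_hotspot,
    splice_context,
)
from .variants import AnnotatedVariant, variant_identity

__all__ = [
    "Criterion",
    "CRITERIA",
    "KnowledgeBase",
    "ClassificationResult",
    "ClassificationError",
    "classify_germline",
    "classify_somatic",
    "tabulate_bins",
    "CADD_THRESHOLD",
    "REVEL_THRESHOLD",
]

#: In-silico thresholds; both comparisons are strict.
CADD_THRESHOLD = 30.0
REVEL_THRESHOLD = 0.75

BINS = ("P", "LP", "VUS", "LB")


class ClassificationError(ValueError):
    """Raised for variants the rule table cannot place (e.g. consequence
    ``other``): the variant needs re-annotation, not a silent bin."""


@dataclass(frozen=True)
class Criterion:
    """The in-silico criterion in force for the LP/LB missense dichotomy.

    ``evaluate`` is three-valued: True (meets the criterion), False (all
    relevant scores present, none meets it), None (every relevant score is
    missing — the variant cannot be scored and falls to VUS).
    """

    name: str  # METASVM | CADD | REVEL | ANY

    def _parts(self, v: AnnotatedVariant) -> list[Optional[bool]]:
        def meta() -> Optional[bool]:
            return None if v.metasvm is None else v.metasvm == "Deleterious"

        def cadd() -> Optional[bool]:
            return None if v.cadd is None else v.cadd > CADD_THRESHOLD

        def revel() -> Optional[bool]:
            return None if v.revel is None else v.revel > REVEL_THRESHOLD

        table = {"METASVM": [meta], "CADD": [cadd], "REVEL": [revel],
                 "ANY": [meta, cadd, revel]}
        if self.name not in table:
            raise ValueError(f"unknown criterion {self.name!r}")
        return [f() for f in table[self.name]]

    def evaluate(self, v: AnnotatedVariant) -> Optional[bool]:
        parts = self._parts(v)
        if any(p is True for p in parts):
            return True
        if all(p is None for p in parts):
            return None
        return False


CRITERIA = {name: Criterion(name) for name in ("METASVM", "CADD", "REVEL", "ANY")}


@dataclass(frozen=True)
class KnowledgeBase:
    """Curated variant identities credibly reported pathogenic.

    Lookup is exact after HGVS canonicalisation through the parsers; no
    positional or fuzzy matching.  Loaded from a two-column delimited file
    (identity, citation).
    """

    entries: frozenset[str] = frozenset()
    citations: dict[str, str] = field(default_factory=dict, compare=False)

    @staticmethod
    def _canonical(identity: str) -> str:
        text = identity.strip()
        for parser in (parse_hgvs_c, parse_hgvs_p):
            try:
                return str(parser(text))
            except ValueError:
                continue
        return text

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "KnowledgeBase":
        canon = {cls._canonical(ident): cite for ident, cite in pairs}
        return cls(entries=frozenset(canon), citations=canon)

    @classmethod
    def from_file(cls, path: str | Path) -> "KnowledgeBase":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        ident_col, cite_col = df.columns[0], df.columns[-1]
        return cls.from_pairs(zip(df[ident_col], df[cite_col].fillna("")))

    def __contains__(self, v: AnnotatedVariant) -> bool:
        candidates = []
        if v.hgvs_c:
            candidates.append(self._canonical(v.hgvs_c))
        if v.hgvs_p is not None:
            candidates.append(str(v.hgvs_p))
        return any(c in self.entries for c in candidates)


@dataclass(frozen=True)
class ClassificationResult:
    """Bin plus the audit trail of rules that fired."""

    bin: str
    rules_fired: tuple[str, ...]
    criterion: str
    notes: str = ""


def _splice_distance(v: AnnotatedVariant, model: TranscriptModel) -> tuple[SpliceRegion, int]:
    """Splice geometry from coordinates, falling back to the c. offset."""
    ctx = splice_context(v.observation.position - 1, model)
    if ctx.region != SpliceRegion.EXONIC or not v.hgvs_c:
        return ctx.region, ctx.intronic_distance
    change = v.coding_change
    if change is not None and change.offset != 0:
        d = abs(change.offset)
        if d <= CANONICAL_SPLICE_MAX:
            return SpliceRegion.CANONICAL_SPLICE, d
        if d <= 9:
            return SpliceRegion.SPLICE_REGION, d
        return SpliceRegion.DEEP_INTRONIC, d
    return ctx.region, ctx.intronic_distance


def _missense_residue(v: AnnotatedVariant, model: TranscriptModel) -> Optional[int]:
    if v.hgvs_p is not None:
        return v.hgvs_p.residue
    return codon_of(v.observation.position - 1, model)


def classify_germline(
    v: AnnotatedVariant,
    model: TranscriptModel,
    registry: HotspotRegistry = DICER1_HOTSPOTS,
    criterion: Criterion = CRITERIA["ANY"],
    kb: Optional[KnowledgeBase] = None,
) -> ClassificationResult:
    """Classify one in-scope germline variant into P/LP/VUS/LB.

    Expects a variant that has passed the scope filter.  P rules are
    evaluated first, in fixed order (LOF, canonical splice, hotspot
    missense, knowledge base); every satisfied P rule is recorded in
    ``rules_fired``.  Only the LP/LB missense dichotomy depends on the
    in-silico ``criterion``; P and VUS calls are criterion-independent.
    """
    if v.observation.origin != "germline":
        raise ValueError(f"classify_germline got a {v.observation.origin} variant")
    if v.consequence == "other":
        raise ClassificationError(
            f"variant {variant_identity(v)} has unusable consequence 'other'; re-annotate"
        )

    region, distance = _splice_distance(v, model)
    fired: list[str] = []
    if v.consequence in ("stop_gained", "frameshift") or (
        v.hgvs_p is not None and v.hgvs_p.is_stop_gained
    ):
        fired.append("LOF")
    if region == SpliceRegion.CANONICAL_SPLICE:
        fired.append("canonical_splice")
    residue = _missense_residue(v, model) if v.consequence == "missense" else None
    if residue is not None and is_hotspot(residue, registry):
        fired.append("hotspot")
    if kb is not None and v in kb:
        fired.append("kb")
    if fired:
        return ClassificationResult("P", tuple(fired), criterion.name)

    if v.consequence == "missense":
        verdict = criterion.evaluate(v)
        if verdict is True:
            return ClassificationResult("LP", ("missense_criterion",), criterion.name)
        if verdict is None:
            return ClassificationResult(
                "VUS", ("missense_scores_missing",), criterion.name,
                notes="all relevant in-silico scores missing",
            )
        return ClassificationResult("LB", ("missense_subthreshold",), criterion.name)

    if region == SpliceRegion.SPLICE_REGION or v.consequence == "splice_region":
        return ClassificationResult("VUS", ("splice_region",), criterion.name)
    if v.consequence == "inframe_deletion":
        return ClassificationResult("VUS", ("inframe_deletion",), criterion.name)
    if v.consequence == "synonymous":
        return ClassificationResult("LB", ("synonymous",), criterion.name)
    raise ClassificationError(
        f"variant {variant_identity(v)} ({v.consequence}) not placeable; re-annotate"
    )


def classify_somatic(
    v: AnnotatedVariant,
    model: TranscriptModel,
    registry: HotspotRegistry = DICER1_HOTSPOTS,
) -> str:
    """Two-rule somatic call: ``"pathogenic"`` or ``"not_pathogenic"``.

    Loss-of-function (nonsense, frameshift, canonical-splice) and hotspot
    missense variation is pathogenic; everything else is not.
    """
    if v.observation.origin != "somatic":
        raise ValueError(f"classify_somatic got a {v.observation.origin} variant")
    if v.consequence in ("stop_gained", "frameshift"):
        return "pathogenic"
    if v.hgvs_p is not None and v.hgvs_p.is_stop_gained:
        return "pathogenic"
    region, _ = _splice_distance(v, model)
    if region == SpliceRegion.CANONICAL_SPLICE:
        return "pathogenic"
    if v.consequence == "missense":
        residue = _missense_residue(v, model)
        if residue is not None and is_hotspot(residue, registry):
            return "pathogenic"
    return "not_pathogenic"


# ---------------------------------------------------------------------------
# tabulation

def _category(v: AnnotatedVariant, result: ClassificationResult) -> str:
    if result.bin == "P":
        rule = result.rules_fired[0]
        if rule == "LOF":
            return v.consequence if v.consequence in ("stop_gained", "frameshift") else "stop_gained"
        if rule == "canonical_splice":
            return v.consequence if v.consequence in ("splice_donor", "splice_acceptor") else "canonical_splice"
        if rule == "hotspot":
            return "hotspot"
        return "knowledge_base"
    if result.bin == "VUS":
        return {"splice_region": "splice_region", "inframe_deletion": "inframe_deletion"}.get(
            result.rules_fired[0], "missense"
        )
    if result.bin == "LB":
        return "synonymous" if v.consequence == "synonymous" else "missense"
    return "missense"


def tabulate_bins(
    variants: Sequence[AnnotatedVariant],
    model: TranscriptModel,
    registry: HotspotRegistry = DICER1_HOTSPOTS,
    criteria: Sequence[Criterion] = (CRITERIA["METASVM"], CRITERIA["CADD"], CRITERIA["REVEL"]),
    kb: Optional[KnowledgeBase] = None,
) -> pd.DataFrame:
    """Unique-variant counts per bin (and category) under each criterion.

    Variants are deduplicated by canonical identity across subjects before
    counting, so a variant shared by several carriers counts once.  Returns
    a tidy frame with columns (criterion, bin, category, n_unique).  P and
    VUS blocks are criterion-independent by construction; LP and LB move
    with the criterion.
    """
    unique: dict[str, AnnotatedVariant] = {}
    for v in variants:
        unique.setdefault(variant_identity(v), v)
    rows = []
    for criterion in criteria:
        counts: dict[tuple[str, str], int] = {}
        for v in unique.values():
            res = classify_germline(v, model, registry, criterion, kb)
            key = (res.bin, _category(v, res))
            counts[key] = counts.get(key, 0) + 1
        for (bin_, cat), n in sorted(counts.items()):
            rows.append(
                {"criterion": criterion.name, "bin": bin_, "category": cat, "n_unique": n}
            )
    return pd.DataFrame(rows, columns=["criterion", "bin", "category", "n_unique"])
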