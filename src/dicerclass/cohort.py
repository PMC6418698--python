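"""Carrier counting, allele counting and 1:N prevalence estimation.

Terminology used throughout:

carrier
    a subject with at least one variant in a given bin; a subject with
    several qualifying variants counts once.
allele count (AC)
    carrier-level variant events per bin.  Co-occurring same-bin variants
    in one subject collapse to a single event (default), while distinct
    subjects sharing the same variant each contribute one — so the
    collapsed AC for a bin equals its carrier count.  A per-variant mode
    (no collapsing) is available but non-default.
prevalence
    reported as the ratio string ``1:D`` with ``D = cohort size /
    carriers`` rounded half-up, either to the nearest integer (tabular
    convention) or to the nearest hundred (narrative convention).
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .classify import ClassificationResult
from .variants import AnnotatedVariant, SubjectRecord, variant_identity

__all__ = [
    "PrevalenceEstimate",
    "CohortSummary",
    "count_carriers",
    "allele_count",
    "prevalence",
    "parse_ratio",
    "summarize_cohort",
]

Classified = tuple[AnnotatedVariant, ClassificationResult]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A 1:D prevalence ratio under a named rounding convention."""

    n_subjects: int
    carriers: int
    denominator: Optional[int]
    rounding: str
    formatted: str


@dataclass(frozen=True)
class CohortSummary:
    """Table-shaped cohort report for one criterion."""

    cohort: str
    criterion: str
    n_subjects: int
    unique_variants: Mapping[str, int]          # bin -> unique identities
    allele_counts: Mapping[str, int]            # bin -> collapsed AC
    carriers: Mapping[str, int]                 # bin -> distinct subjects
    carriers_by_type: Mapping[str, int]         # cancer type -> P/LP carriers
    type_fractions: Mapping[str, str]           # cancer type -> "x.x% (c/N)"
    carrier_roster: tuple[tuple[str, str, str, str], ...]  # subject, type, variant, bin


def count_carriers(
    classified: Iterable[tuple[str, ClassificationResult]], bins: set[str]
) -> int:
    """Distinct subjects with at least one variant in the given bins."""
    return len({subject for subject, res in classified if res.bin in bins})


def allele_count(
    classified: Iterable[Classified], bin: str, collapse_within_subject: bool = True
) -> int:
    """Carrier-level allele-count events for one bin.

    With collapsing (default), a subject carrying two same-bin variants
    contributes one event; distinct subjects sharing a variant each count.
    """
    hits = [(v.subject_id, variant_identity(v)) for v, res in classified if res.bin == bin]
    if collapse_within_subject:
        return len({subject for subject, _ in hits})
    return len(hits)


def prevalence(
    n_subjects: int, carriers: int, rounding: str = "nearest_int"
) -> PrevalenceEstimate:
    """1:D prevalence with half-up rounding to an integer or a hundred.

    Zero carriers yields an explicit no-carriers estimate (denominator
    None) rather than a division error.
    """
    if rounding not in ("nearest_int", "nearest_hundred"):
        raise ValueError(f"unknown rounding convention {rounding!r}")
    if carriers < 0 or n_subjects < carriers:
        raise ValueError("need 0 <= carriers <= n_subjects")
    if carriers == 0:
        return PrevalenceEstimate(n_subjects, 0, None, rounding, "no carriers")
    ratio = n_subjects / carriers
    if rounding == "nearest_hundred":
        denom = _round_half_up(ratio / 100) * 100
    else:
        denom = _round_half_up(ratio)
    return PrevalenceEstimate(n_subjects, carriers, denom, rounding, f"1:{denom:,}")


def parse_ratio(formatted: str) -> int:
    """Recover the denominator from a ``1:D`` string (inverse of formatting)."""
    m = re.match(r"^1:([\d,]+)$", formatted.strip())
    if not m:
        raise ValueError(f"not a 1:D ratio string: {formatted!r}")
    return int(m.group(1).replace(",", ""))


def summarize_cohort(
    classified: Sequence[Classified],
    subjects: Sequence[SubjectRecord],
    criterion: str = "ANY",
    cohort: str = "",
    n_subjects: Optional[int] = None,
    type_sizes: Optional[Mapping[str, int]] = None,
) -> CohortSummary:
    """Per-bin and per-cancer-type counts for one cohort.

    ``subjects`` is the carrier roster (it may be the full cohort); the
    cohort size used for prevalence is ``n_subjects`` when the roster is a
    carrier subset.  ``type_sizes`` supplies per-cancer-type denominators
    for the fraction report — carriers are a subset, so totals must come
    from the roster side, never from the variant data.
    """
    roster = {s.subject_id: s for s in subjects}
    for v, _ in classified:
        if v.subject_id not in roster:
            raise KeyError(
                f"variant subject {v.subject_id!r} absent from the subject roster"
            )
    n = n_subjects if n_subjects is not None else len(roster)

    unique: dict[str, set[str]] = defaultdict(set)
    carriers: dict[str, set[str]] = defaultdict(set)
    for v, res in classified:
        unique[res.bin].add(variant_identity(v))
        carriers[res.bin].add(v.subject_id)

    plp_by_type: dict[str, set[str]] = defaultdict(set)
    roster_rows = []
    for v, res in classified:
        if res.bin in ("P", "LP"):
            ctype = roster[v.subject_id].cancer_type
            plp_by_type[ctype].add(v.subject_id)
            roster_rows.append((v.subject_id, ctype, variant_identity(v), res.bin))

    fractions = {}
    if type_sizes:
        for ctype, total in type_sizes.items():
            c = len(plp_by_type.get(ctype, ()))
            if c:
                fractions[ctype] = f"{100 * c / total:.1f}% ({c}/{total})"

    return CohortSummary(
        cohort=cohort,
        criterion=criterion,
        n_subjects=n,
        unique_variants={b: len(s) for b, s in unique.items()},
        allele_counts={b: allele_count(classified, b) for b in unique},
        carriers={b: len(s) for b, s in carriers.items()},
        carriers_by_type={t: len(s) for t, s in sorted(plp_by_type.items())},
        type_fractions=fractions,
        carrier_roster=tuple(sorted(set(roster_rows))),
    )
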