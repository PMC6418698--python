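"""Packaged cohort fixtures: the published TCGA carrier roster and the
pediatric (TARGET) cohort summary.

Two fixtures are shipped as human-auditable tab-delimited tables:

``tcga``
    The 19 published germline P/LP variant observations across 18 TCGA
    subjects (16 unique variants; one uterine-carcinoma subject carries
    both a hotspot missense and a splice-donor variant), with the two
    somatic co-variants of one subject, subject demographics, the
    per-cancer-type cohort sizes, and the cohort size of 9,173 exomes.
    Per-variant in-silico flags are a documented reconstruction: the
    published report gives only the aggregate breakdown (9 unique missense
    by metaSVM with allele count 11, 5 by CADD, 1 by REVEL), and the
    packaged flags are one assignment consistent with those aggregates.

``target``
    The pediatric cohort: 175 exomes over neuroblastoma (142) and Wilms
    tumor (33), with two likely-pathogenic missense carriers — both
    metaSVM "Deleterious", one with CADD > 30, none above the REVEL
    threshold.  Variant identities in this fixture are synthetic
    stand-ins (the published source does not print them); counts and
    score flags are the load-bearing content.

The packaged transcript model is a synthetic stand-in for RefSeq
NM_177438.2 with faithful structure (27 exons, minus strand, 1922-residue
protein) but synthetic exon/intron sizes; all fixture coordinates are
generated against it, so geometry and annotations are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .transcript import TranscriptModel, load_transcript
from .variants import AnnotatedVariant, SubjectRecord, read_variants

__all__ = [
    "PublishedCohort",
    "load_published_cohort",
    "packaged_transcript",
    "TCGA_COHORT_SIZE",
    "TARGET_COHORT_SIZE",
]

#: Cohort sizes of the two analysed exome cohorts.
TCGA_COHORT_SIZE = 9_173
TARGET_COHORT_SIZE = 175

_DATA = resources.files("dicerclass") / "data"


@dataclass(frozen=True)
class PublishedCohort:
    """A packaged cohort: variants, subjects, and cohort denominators."""

    name: str
    variants: tuple[AnnotatedVariant, ...]          # germline observations
    somatic_variants: tuple[AnnotatedVariant, ...]  # somatic co-variants
    subjects: tuple[SubjectRecord, ...]             # carrier roster
    cohort_n: int
    type_sizes: Mapping[str, int]                   # cancer type -> cohort N


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def packaged_transcript() -> TranscriptModel:
    """The packaged (synthetic stand-in) NM_177438.2 transcript model."""
    return load_transcript(_data_path("NM_177438.2.synthetic.genepred"))


def _read_subjects(name: str, cohort: str) -> tuple[SubjectRecord, ...]:
    df = pd.read_csv(_data_path(name), sep="\t", dtype=str, comment="#", keep_default_na=False)
    return tuple(
        SubjectRecord(
            subject_id=r["subject_id"],
            cohort=cohort,
            cancer_type=r["cancer_type"],
            sex=r.get("sex", ""),
            age_at_diagnosis=float(r["age_at_diagnosis"]) if r.get("age_at_diagnosis") else None,
            race=r.get("race", ""),
            vital_status=r.get("vital_status", ""),
        )
        for r in df.to_dict("records")
    )


def _read_type_sizes(name: str) -> dict[str, int]:
    df = pd.read_csv(_data_path(name), sep="\t", comment="#")
    return dict(zip(df["cancer_type"], df["n"].astype(int)))


def load_published_cohort(which: str) -> PublishedCohort:
    """Load a packaged cohort fixture: ``tcga`` or ``target``."""
    if which == "tcga":
        return PublishedCohort(
            name=which,
            variants=tuple(read_variants(_data_path("tcga_carriers.tsv"))),
            somatic_variants=tuple(read_variants(_data_path("tcga_somatic.tsv"))),
            subjects=_read_subjects("tcga_subjects.tsv", cohort="TCGA"),
            cohort_n=TCGA_COHORT_SIZE,
            type_sizes=_read_type_sizes("tcga_type_sizes.tsv"),
        )
    if which == "target":
        return PublishedCohort(
            name=which,
            variants=tuple(read_variants(_data_path("target_variants.tsv"))),
            somatic_variants=(),
            subjects=_read_subjects("target_subjects.tsv", cohort="TARGET"),
            cohort_n=TARGET_COHORT_SIZE,
            type_sizes=_read_type_sizes("target_type_sizes.tsv"),
        )
    raise ValueError(f"unknown fixture {which!r}; use 'tcga' or 'target'")
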