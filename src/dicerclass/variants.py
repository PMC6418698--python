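"""Annotated variant observations: containers, file I/O, consensus, scope.

An *observation* is one variant seen in one subject.  Annotations
(molecular consequence, HGVS, in-silico scores, population frequencies)
are consumed as input fields — this package never recomputes them.

Two on-disk dialects are supported and round-trip losslessly:

* a tab-delimited table (UTF-8, documented header, one observation per
  row, empty field = missing) — the packaged fixtures use this form so
  they stay human-auditable;
* VCF 4.2 with the annotations in INFO keys (one record per observation).

Missing in-silico scores are represented as ``None`` and are never
imputed; the classifier treats a missing score differently from a low one.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .hgvs import CodingChange, ProteinChange, parse_hgvs_c, parse_hgvs_p
from .transcript import SpliceRegion, TranscriptModel, splice_context

__all__ = [
    "VariantObservation",
    "AnnotatedVariant",
    "SubjectRecord",
    "CONSEQUENCES",
    "VariantFileError",
    "read_variants",
    "write_variants",
    "consensus_merge",
    "scope_filter",
    "variant_identity",
    "TSV_COLUMNS",
]

#: Recognised molecular-consequence vocabulary.  Anything else is recorded
#: as ``other`` with a warning and rejected by the classifier.
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gained",
        "frameshift",
        "synonymous",
        "splice_donor",
        "splice_acceptor",
        "splice_region",
        "inframe_deletion",
        "other",
    }
)

#: Population allele-frequency sources carried through unchanged.
AF_SOURCES = ("exac_nontcga", "esp", "1kg")


class VariantFileError(ValueError):
    """Raised for malformed variant files (carries the offending line)."""


@dataclass(frozen=True)
class VariantObservation:
    """One variant call in one subject (coordinates 1-based, as in VCF)."""

    subject_id: str
    cohort: str
    cancer_type: str
    origin: str  # "germline" | "somatic"
    chromosome: str
    position: int
    ref: str
    alt: str
    callers: frozenset[str] = frozenset()
    zygosity: str = "unknown"  # "het" | "hom" | "unknown"

    def __post_init__(self) -> None:
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline/somatic, got {self.origin!r}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity used for consensus merging and multi-allelic grouping."""
        return (self.subject_id, self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant observation plus the annotations the classifier consumes."""

    observation: VariantObservation
    consequence: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[ProteinChange] = None
    metasvm: Optional[str] = None  # "Deleterious" | "Tolerated" | None
    cadd: Optional[float] = None
    revel: Optional[float] = None
    pop_af: Mapping[str, float] = field(default_factory=dict)
    kb_assertion: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence == "stop_gained" and self.hgvs_p is not None:
            if not self.hgvs_p.is_stop_gained:
                raise ValueError(
                    f"stop_gained variant with non-stop protein change {self.hgvs_p}"
                )

    @property
    def coding_change(self) -> Optional[CodingChange]:
        """Parsed c. substitution, or None (also for non-substitution c.)."""
        if not self.hgvs_c:
            return None
        try:
            return parse_hgvs_c(self.hgvs_c)
        except ValueError:
            return None

    @property
    def subject_id(self) -> str:
        return self.observation.subject_id


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic payload for one cohort subject; never used by any rule."""

    subject_id: str
    cohort: str
    cancer_type: str
    sex: str = ""
    age_at_diagnosis: Optional[float] = None
    race: str = ""
    vital_status: str = ""


def variant_identity(v: AnnotatedVariant) -> str:
    """Canonical identity for deduplicating a variant across subjects.

    Prefers the c. notation (canonicalised through the parser), falls back
    to the protein change, then to raw coordinates.
    """
    if v.hgvs_c:
        try:
            return str(parse_hgvs_c(v.hgvs_c))
        except ValueError:
            return v.hgvs_c.strip()
    if v.hgvs_p is not None:
        return str(v.hgvs_p)
    o = v.observation
    return f"{o.chromosome}:{o.position}{o.ref}>{o.alt}"


# ---------------------------------------------------------------------------
# tabular dialect

TSV_COLUMNS = [
    "subject_id", "cohort", "cancer_type", "origin", "chromosome", "position",
    "ref", "alt", "callers", "zygosity", "consequence", "hgvs_c", "hgvs_p",
    "metasvm", "cadd", "revel", "af_exac_nontcga", "af_esp", "af_1kg", "kb",
]


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _row_to_variant(row: Mapping, line_no: int) -> AnnotatedVariant:
    try:
        consequence = _opt(row.get("consequence")) or "other"
        if consequence not in CONSEQUENCES:
            warnings.warn(
                f"line {line_no}: unknown consequence {consequence!r}, recording as 'other'",
                stacklevel=4,
            )
            consequence = "other"
        callers = _opt(row.get("callers"))
        obs = VariantObservation(
            subject_id=str(row["subject_id"]),
            cohort=str(row.get("cohort", "")),
            cancer_type=str(row.get("cancer_type", "")),
            origin=str(row["origin"]),
            chromosome=str(row["chromosome"]),
            position=int(row["position"]),
            ref=str(row["ref"]).upper(),
            alt=str(row["alt"]).upper(),
            callers=frozenset(callers.split("|")) if callers else frozenset(),
            zygosity=_opt(row.get("zygosity")) or "unknown",
        )
        hgvs_p_text = _opt(row.get("hgvs_p"))
        pop_af = {}
        for src in AF_SOURCES:
            val = _opt(row.get(f"af_{src}"))
            if val is not None:
                pop_af[src] = float(val)
        cadd = _opt(row.get("cadd"))
        revel = _opt(row.get("revel"))
        return AnnotatedVariant(
            observation=obs,
            consequence=consequence,
            hgvs_c=_opt(row.get("hgvs_c")),
            hgvs_p=parse_hgvs_p(hgvs_p_text) if hgvs_p_text else None,
            metasvm=_opt(row.get("metasvm")),
            cadd=float(cadd) if cadd is not None else None,
            revel=float(revel) if revel is not None else None,
            pop_af=pop_af,
            kb_assertion=(_opt(row.get("kb")) or "").lower() in ("1", "true", "yes"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise VariantFileError(f"line {line_no}: {exc}") from exc


def _read_tsv(path: Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = {"subject_id", "origin", "chromosome", "position", "ref", "alt"} - set(df.columns)
    if missing:
        raise VariantFileError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        out.append(_row_to_variant(row, line_no=i + 2))
    return out


def _write_tsv(variants: Sequence[AnnotatedVariant], path: Path) -> None:
    rows = []
    for v in variants:
        o = v.observation
        rows.append(
            {
                "subject_id": o.subject_id,
                "cohort": o.cohort,
                "cancer_type": o.cancer_type,
                "origin": o.origin,
                "chromosome": o.chromosome,
                "position": o.position,
                "ref": o.ref,
                "alt": o.alt,
                "callers": "|".join(sorted(o.callers)),
                "zygosity": o.zygosity,
                "consequence": v.consequence,
                "hgvs_c": v.hgvs_c or "",
                "hgvs_p": str(v.hgvs_p) if v.hgvs_p else "",
                "metasvm": v.metasvm or "",
                "cadd": "" if v.cadd is None else repr(float(v.cadd)),
                "revel": "" if v.revel is None else repr(float(v.revel)),
                **{
                    f"af_{src}": ("" if v.pop_af.get(src) is None else repr(float(v.pop_af[src])))
                    for src in AF_SOURCES
                },
                "kb": "1" if v.kb_assertion else "",
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect (one record per observation; annotations in INFO)

_VCF_INFO = [
    ("SUBJECT", "String", "Subject identifier"),
    ("COHORT", "String", "Cohort name"),
    ("CANCER_TYPE", "String", "Cancer type label"),
    ("ORIGIN", "String", "germline or somatic"),
    ("CALLERS", "String", "Pipe-separated supporting caller labels"),
    ("ZYG", "String", "Zygosity"),
    ("CONSEQUENCE", "String", "Molecular consequence"),
    ("HGVSC", "String", "HGVS c. notation"),
    ("HGVSP", "String", "HGVS p. notation"),
    ("METASVM", "String", "metaSVM category"),
    ("CADD", "Float", "Scaled CADD score"),
    ("REVEL", "Float", "REVEL score"),
    ("AF_EXAC_NONTCGA", "Float", "ExAC non-TCGA allele frequency"),
    ("AF_ESP", "Float", "ESP allele frequency"),
    ("AF_1KG", "Float", "1000 Genomes allele frequency"),
    ("KB", "Flag", "Asserted published-pathogenic in the knowledge base"),
]

_AF_INFO_KEY = {"exac_nontcga": "AF_EXAC_NONTCGA", "esp": "AF_ESP", "1kg": "AF_1KG"}


def _vcf_float(value) -> Optional[float]:
    """Recover the shortest decimal of a VCF Float (stored as 32-bit).

    VCF Float INFO values pass through float32, so scores round-trip at
    float32 precision; decoding the shortest round-trip decimal makes
    values written with few significant digits (every realistic score)
    come back exactly.
    """
    import numpy as np

    if value is None:
        return None
    return float(np.format_float_positional(np.float32(value), unique=True, trim="-"))


def _read_vcf(path: Path) -> list[AnnotatedVariant]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for alt in rec.alts or ():
                row = {
                    "subject_id": info.get("SUBJECT"),
                    "cohort": info.get("COHORT") or "",
                    "cancer_type": info.get("CANCER_TYPE") or "",
                    "origin": info.get("ORIGIN"),
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "callers": info.get("CALLERS") or "",
                    "zygosity": info.get("ZYG") or "",
                    "consequence": info.get("CONSEQUENCE") or "",
                    "hgvs_c": info.get("HGVSC") or "",
                    "hgvs_p": info.get("HGVSP") or "",
                    "metasvm": info.get("METASVM") or "",
                    "cadd": _vcf_float(info.get("CADD")),
                    "revel": _vcf_float(info.get("REVEL")),
                    "af_exac_nontcga": _vcf_float(info.get("AF_EXAC_NONTCGA")),
                    "af_esp": _vcf_float(info.get("AF_ESP")),
                    "af_1kg": _vcf_float(info.get("AF_1KG")),
                    "kb": "1" if info.get("KB") else "",
                }
                out.append(_row_to_variant(row, line_no=rec.pos))
    return out


def _write_vcf(variants: Sequence[AnnotatedVariant], path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    for chrom in sorted({v.observation.chromosome for v in variants}):
        header.contigs.add(chrom)
    for key, typ, desc in _VCF_INFO:
        number = 0 if typ == "Flag" else 1
        header.info.add(key, number, typ, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            o = v.observation
            rec = vcf.new_record(
                contig=o.chromosome, start=o.position - 1, alleles=(o.ref, o.alt)
            )
            rec.info["SUBJECT"] = o.subject_id
            if o.cohort:
                rec.info["COHORT"] = o.cohort
            if o.cancer_type:
                rec.info["CANCER_TYPE"] = o.cancer_type
            rec.info["ORIGIN"] = o.origin
            if o.callers:
                rec.info["CALLERS"] = "|".join(sorted(o.callers))
            rec.info["ZYG"] = o.zygosity
            rec.info["CONSEQUENCE"] = v.consequence
            if v.hgvs_c:
                rec.info["HGVSC"] = v.hgvs_c
            if v.hgvs_p is not None:
                rec.info["HGVSP"] = str(v.hgvs_p)
            if v.metasvm:
                rec.info["METASVM"] = v.metasvm
            if v.cadd is not None:
                rec.info["CADD"] = float(v.cadd)
            if v.revel is not None:
                rec.info["REVEL"] = float(v.revel)
            for src, key in _AF_INFO_KEY.items():
                if src in v.pop_af:
                    rec.info[key] = float(v.pop_af[src])
            if v.kb_assertion:
                rec.info["KB"] = True
            vcf.write(rec)


def read_variants(path: str | Path, dialect: Optional[str] = None) -> list[AnnotatedVariant]:
    """Read annotated variant observations from a VCF or tab-delimited table.

    ``dialect`` is ``"vcf"`` or ``"tsv"``; when omitted it is inferred from
    the file extension.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variants(
    variants: Sequence[AnnotatedVariant], path: str | Path, dialect: Optional[str] = None
) -> None:
    """Write observations in the chosen dialect (inverse of read_variants)."""
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        _write_vcf(variants, path)
    elif dialect == "tsv":
        _write_tsv(variants, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# consensus merging


def consensus_merge(
    call_sets: Mapping[str, Sequence[VariantObservation]], min_callers: int = 2
) -> list[VariantObservation]:
    """Keep observations reported by at least ``min_callers`` callers.

    ``call_sets`` maps a caller label to its observations.  Observations are
    matched on (subject, chromosome, position, ref, alt); retained
    observations carry the union of supporting caller labels.  Duplicates
    within one caller's set count once; output order is deterministic
    (sorted by key) and independent of caller ordering.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    support: dict[tuple, set[str]] = defaultdict(set)
    exemplar: dict[tuple, VariantObservation] = {}
    for caller in sorted(call_sets):
        for obs in call_sets[caller]:
            support[obs.key].add(caller)
            exemplar.setdefault(obs.key, obs)
    out = []
    for key in sorted(support):
        if len(support[key]) >= min_callers:
            out.append(replace(exemplar[key], callers=frozenset(support[key])))
    return out


# ---------------------------------------------------------------------------
# scope filter


def scope_filter(
    variants: Sequence[AnnotatedVariant], model: TranscriptModel
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, str]]]:
    """Restrict to exonic coding and splice-site-region variants.

    Returns ``(kept, excluded)`` where ``excluded`` pairs each dropped
    variant with a reason: ``multi_allelic`` (more than one alternate
    allele at a subject's site, evaluated after decomposition),
    ``deep_intronic`` (10 or more intronic bases from the nearest
    junction), or ``utr`` (exonic but outside the CDS).  The two lists
    partition the input.
    """
    by_site: dict[tuple, set[str]] = defaultdict(set)
    for v in variants:
        o = v.observation
        by_site[(o.subject_id, o.chromosome, o.position)].add(o.alt)

    kept: list[AnnotatedVariant] = []
    excluded: list[tuple[AnnotatedVariant, str]] = []
    for v in variants:
        o = v.observation
        if len(by_site[(o.subject_id, o.chromosome, o.position)]) > 1:
            excluded.append((v, "multi_allelic"))
            continue
        ctx = splice_context(o.position - 1, model)
        if ctx.region == SpliceRegion.DEEP_INTRONIC:
            excluded.append((v, "deep_intronic"))
        elif ctx.region == SpliceRegion.EXONIC and model.is_utr(o.position - 1):
            excluded.append((v, "utr"))
        else:
            kept.append(v)
    return kept, excluded
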