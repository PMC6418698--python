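"""Synthetic annotated cohorts with known ground-truth classifications.

The generator emulates the variant universe the classifier operates on —
loss-of-function, canonical-splice, splice-region, hotspot and
non-hotspot missense, synonymous, in-frame deletion, plus the
out-of-scope classes (deep intronic, UTR, multi-allelic) — with
per-caller detection noise and configurable per-bin carrier fractions.
Every generated variant is geometrically consistent with the transcript
model (a canonical-splice variant really lies 1-2 intronic bp from a
junction; a hotspot variant's codon maps to a registry residue), and a
:class:`GroundTruth` records the bin each variant must receive under each
in-silico criterion, so every pipeline stage is testable without any
external data.

Score distributions are deliberately two-component, straddling the CADD,
REVEL and metaSVM decision boundaries, so both sides of every threshold
are exercised; they are test instruments, not estimates of real score
distributions.  Default carrier fractions mirror the analysed adult
cancer cohort (about 2 pathogenic and 13 likely-pathogenic carriers per
9,173 subjects); benign and uncertain fractions are set to realistic
rare-gene screening levels (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .hgvs import AA_1TO3, ProteinChange, parse_hgvs_p
from .transcript import (
    DICER1_HOTSPOTS,
    HotspotRegistry,
    TranscriptModel,
)
from .variants import AnnotatedVariant, SubjectRecord, VariantObservation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "VariantTruth",
    "generate_cohort",
    "degrade_annotations",
    "caller_call_sets",
    "CLASSES",
    "BIN_CLASSES",
]

#: Variant classes the generator can emit.
CLASSES = (
    "lof",
    "canonical_splice",
    "hotspot_missense",
    "nonhotspot_missense",
    "splice_region",
    "synonymous",
    "inframe_deletion",
    "deep_intronic",
    "utr",
    "multi_allelic",
)

#: Which classes realise each intended bin ("excluded" = out of scope).
BIN_CLASSES = {
    "P": ("lof", "canonical_splice", "hotspot_missense"),
    "LP": ("nonhotspot_missense",),
    "VUS": ("splice_region", "inframe_deletion"),
    "LB": ("synonymous", "nonhotspot_missense"),
    "excluded": ("deep_intronic", "utr", "multi_allelic"),
}

_CALLERS = ("FreeBayes", "HaplotypeCaller", "UnifiedGenotyper")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_AA = [a for a in AA_1TO3 if a != "*"]


class SimulationConfig(BaseModel):
    """Deterministic cohort-generation parameters.

    Identical ``seed`` plus identical parameters give byte-identical
    cohorts.  ``bin_carrier_fractions`` is the per-subject Bernoulli
    probability of carrying one variant of each intended bin;
    ``class_proportions`` (summing to 1 over all classes) sets the mix of
    classes within a bin after renormalisation.
    """

    model_config = {"frozen": True}

    seed: int = 0
    n_subjects: int = Field(default=1000, ge=1)
    cancer_type_weights: dict[str, float] = Field(
        default={"BRCA": 0.25, "LUAD": 0.2, "HNSC": 0.2, "UCEC": 0.15, "THCA": 0.1, "READ": 0.1}
    )
    bin_carrier_fractions: dict[str, float] = Field(
        default={"P": 2 / 9173, "LP": 13 / 9173, "VUS": 0.004, "LB": 0.03, "excluded": 0.01}
    )
    class_proportions: dict[str, float] = Field(
        default={
            "lof": 0.010,
            "canonical_splice": 0.008,
            "hotspot_missense": 0.002,
            "nonhotspot_missense": 0.350,
            "splice_region": 0.200,
            "synonymous": 0.300,
            "inframe_deletion": 0.020,
            "deep_intronic": 0.060,
            "utr": 0.030,
            "multi_allelic": 0.020,
        }
    )
    # probability an LP-intent missense satisfies each predictor (resampled
    # until at least one holds); realised scores straddle the thresholds
    p_metasvm_deleterious: float = Field(default=0.6, ge=0, le=1)
    p_cadd_deleterious: float = Field(default=0.4, ge=0, le=1)
    p_revel_deleterious: float = Field(default=0.15, ge=0, le=1)
    cadd_deleterious_range: tuple[float, float] = (30.5, 45.0)
    cadd_benign_range: tuple[float, float] = (1.0, 25.0)
    revel_deleterious_range: tuple[float, float] = (0.76, 0.99)
    revel_benign_range: tuple[float, float] = (0.0, 0.60)
    score_missingness: dict[str, float] = Field(
        default={"metasvm": 0.0, "cadd": 0.0, "revel": 0.0}
    )
    caller_sensitivity: dict[str, float] = Field(default={c: 1.0 for c in _CALLERS})
    caller_false_call_rate: dict[str, float] = Field(default={c: 0.0 for c in _CALLERS})

    @field_validator("bin_carrier_fractions", "score_missingness",
                     "caller_sensitivity", "caller_false_call_rate")
    @classmethod
    def _rates_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for key, rate in v.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {key}={rate} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _proportions_sum_to_one(self) -> "SimulationConfig":
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown variant classes {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        return self


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one generated observation."""

    variant_class: str
    in_scope: bool
    bins: Mapping[str, str]  # criterion name -> intended bin (or "excluded")
    callers: frozenset[str]


@dataclass
class GroundTruth:
    """Per-observation truth keyed by (subject_id, variant identity)."""

    records: dict[tuple[str, str], VariantTruth] = field(default_factory=dict)

    def carriers(self, bins: set[str], criterion: str = "ANY") -> set[str]:
        return {
            subject
            for (subject, _), t in self.records.items()
            if t.in_scope and t.bins[criterion] in bins
        }

    def unique_variants(self, bin: str, criterion: str = "ANY") -> set[str]:
        return {
            ident
            for (_, ident), t in self.records.items()
            if t.in_scope and t.bins[criterion] == bin
        }


# ---------------------------------------------------------------------------
# generation internals


def _threshold_bins(
    metasvm: Optional[str], cadd: Optional[float], revel: Optional[float]
) -> dict[str, str]:
    """Intended bin of a non-hotspot missense under each criterion.

    Written out from the threshold definitions (Deleterious, >30, >0.75)
    rather than by calling the classifier, so generator truth stays an
    independent construction.
    """
    parts = {
        "METASVM": None if metasvm is None else metasvm == "Deleterious",
        "CADD": None if cadd is None else cadd > 30.0,
        "REVEL": None if revel is None else revel > 0.75,
    }
    out = {}
    for name in ("METASVM", "CADD", "REVEL"):
        p = parts[name]
        out[name] = "VUS" if p is None else ("LP" if p else "LB")
    vals = list(parts.values())
    if any(v is True for v in vals):
        out["ANY"] = "LP"
    elif all(v is None for v in vals):
        out["ANY"] = "VUS"
    else:
        out["ANY"] = "LB"
    return out


class _Generator:
    def __init__(self, config: SimulationConfig, model: TranscriptModel,
                 registry: HotspotRegistry = DICER1_HOTSPOTS):
        self.cfg = config
        self.model = model
        self.registry = registry
        self.rng = np.random.default_rng(config.seed)
        self.hotspots = sorted(registry.residues())
        self.hotspot_ref = dict(registry.entries)
        # introns as (left exon end, right exon start), genomic
        self.introns = [
            (e1, s2) for (_, e1), (s2, _) in zip(model.exons, model.exons[1:])
        ]

    # -- low-level samplers ----------------------------------------------
    def _bases(self, n: int = 1) -> str:
        return "".join(self.rng.choice(list(_BASES), size=n))

    def _substitution(self) -> tuple[str, str]:
        ref = self._bases()
        alt = ref
        while alt == ref:
            alt = self._bases()
        return ref, alt

    def _genomic_alleles(self, ref_c: str, alt_c: str) -> tuple[str, str]:
        if self.model.strand == "-":
            return ref_c.translate(_COMP), alt_c.translate(_COMP)
        return ref_c, alt_c

    def _random_residue(self, avoid_hotspots: bool = True) -> int:
        while True:
            r = int(self.rng.integers(2, self.model.protein_length))
            if not (avoid_hotspots and r in self.registry):
                return r

    def _intronic_position(self, distance_range: tuple[int, int]):
        """Random intronic base at a distance in the given range from its
        *nearest* junction; returns (genomic pos, c. position, offset)."""
        while True:
            i = int(self.rng.integers(0, len(self.introns)))
            left_end, right_start = self.introns[i]
            half = (right_start - left_end) // 2
            lo, hi = distance_range
            hi = min(hi, half - 1 if (right_start - left_end) % 2 == 0 else half)
            if hi < lo:
                continue
            d = int(self.rng.integers(lo, hi + 1))
            if self.rng.random() < 0.5:
                g, g_ex = left_end - 1 + d, left_end - 1
            else:
                g, g_ex = right_start - d, right_start
            c = self.model.c_of_genomic(g_ex)
            if c is None:  # UTR-flanking intron edge; resample
                continue
            offset = d if self.model.genomic_of_c(c, d) == g else -d
            return g, c, offset

    # -- class builders ----------------------------------------------------
    def _make_variant(self, subject: SubjectRecord, clazz: str, intent: str,
                      used_positions: set[int]) -> list[tuple[AnnotatedVariant, VariantTruth]]:
        cfg, model = self.cfg, self.model
        metasvm = cadd = revel = None
        hgvs_c = None
        hgvs_p: Optional[ProteinChange] = None
        bins: dict[str, str]
        in_scope = True
        alleles_c = self._substitution()

        if clazz in ("lof", "hotspot_missense", "nonhotspot_missense", "synonymous",
                     "inframe_deletion"):
            residue = (
                int(self.rng.choice(self.hotspots))
                if clazz == "hotspot_missense"
                else self._random_residue()
            )
            codon_base = {"synonymous": 3}.get(clazz, int(self.rng.integers(1, 3)))
            c_pos = 3 * (residue - 1) + codon_base
            g = model.genomic_of_c(c_pos)
        elif clazz in ("canonical_splice", "splice_region", "deep_intronic"):
            rng_map = {"canonical_splice": (1, 2), "splice_region": (3, 9),
                       "deep_intronic": (10, 200)}
            g, c_pos, offset = self._intronic_position(rng_map[clazz])
        else:  # utr, multi_allelic
            if clazz == "utr":
                cds0 = model.tx_offset(model.cds_start if model.strand == "+" else model.cds_end - 1)
                utr_offsets = list(range(0, cds0)) + list(
                    range(cds0 + model.cds_length, sum(e - s for s, e in model.exons))
                )
                g = model.genomic_of_tx(int(self.rng.choice(utr_offsets)))
            else:  # multi-allelic: reuse a random synonymous-style coding site
                residue = self._random_residue()
                g = model.genomic_of_c(3 * (residue - 1) + 3)

        if g in used_positions:
            return []  # extremely rare collision; skip rather than mislabel
        used_positions.add(g)

        if clazz == "lof":
            if self.rng.random() < 0.5:
                consequence = "stop_gained"
                hgvs_c = f"c.{c_pos}{alleles_c[0]}>{alleles_c[1]}"
                hgvs_p = ProteinChange(str(self.rng.choice(_AA)), residue, "*")
            else:
                consequence = "frameshift"
                hgvs_c = f"c.{c_pos}del"
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "P")
        elif clazz == "canonical_splice":
            consequence = "splice_donor" if offset > 0 else "splice_acceptor"
            hgvs_c = f"c.{c_pos}{offset:+d}{alleles_c[0]}>{alleles_c[1]}"
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "P")
        elif clazz == "hotspot_missense":
            consequence = "missense"
            hgvs_c = f"c.{c_pos}{alleles_c[0]}>{alleles_c[1]}"
            ref_aa = self.hotspot_ref[residue]
            alt_aa = ref_aa
            while alt_aa == ref_aa:
                alt_aa = str(self.rng.choice(_AA))
            hgvs_p = ProteinChange(ref_aa, residue, alt_aa)
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "P")
        elif clazz == "nonhotspot_missense":
            consequence = "missense"
            hgvs_c = f"c.{c_pos}{alleles_c[0]}>{alleles_c[1]}"
            ref_aa = str(self.rng.choice(_AA))
            alt_aa = ref_aa
            while alt_aa == ref_aa:
                alt_aa = str(self.rng.choice(_AA))
            hgvs_p = ProteinChange(ref_aa, residue, alt_aa)
            metasvm, cadd, revel = self._missense_scores(deleterious=intent == "LP")
            bins = _threshold_bins(metasvm, cadd, revel)
        elif clazz == "splice_region":
            consequence = "splice_region"
            hgvs_c = f"c.{c_pos}{offset:+d}{alleles_c[0]}>{alleles_c[1]}"
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "VUS")
        elif clazz == "synonymous":
            consequence = "synonymous"
            hgvs_c = f"c.{c_pos}{alleles_c[0]}>{alleles_c[1]}"
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "LB")
        elif clazz == "inframe_deletion":
            consequence = "inframe_deletion"
            hgvs_c = f"c.{c_pos}_{c_pos + 2}del"
            alleles_c = (self._bases(4), self._bases(1))
            bins = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "VUS")
        elif clazz == "deep_intronic":
            consequence = "other"
            hgvs_c = f"c.{c_pos}{offset:+d}{alleles_c[0]}>{alleles_c[1]}"
            bins, in_scope = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "excluded"), False
        elif clazz == "utr":
            consequence = "other"
            bins, in_scope = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "excluded"), False
        else:  # multi_allelic: two alternates at one site
            consequence = "synonymous"
            hgvs_c = None
            bins, in_scope = dict.fromkeys(("METASVM", "CADD", "REVEL", "ANY"), "excluded"), False

        support = frozenset(
            c for c in self.cfg.caller_sensitivity
            if self.rng.random() < self.cfg.caller_sensitivity[c]
        )
        out = []
        if clazz == "multi_allelic":
            ref = self._bases()
            alts = list(self.rng.choice([b for b in _BASES if b != ref], size=2, replace=False))
            for alt in alts:
                obs = self._observation(subject, g, ref, alt, support)
                v = AnnotatedVariant(observation=obs, consequence=consequence)
                truth = VariantTruth(clazz, in_scope, bins, support)
                out.append((v, truth))
            return out

        ref_g, alt_g = self._genomic_alleles(*alleles_c) if len(alleles_c[0]) == 1 else alleles_c
        obs = self._observation(subject, g, ref_g, alt_g, support)
        metasvm, cadd, revel = self._apply_missingness(metasvm, cadd, revel)
        if clazz == "nonhotspot_missense":
            bins = _threshold_bins(metasvm, cadd, revel)
        v = AnnotatedVariant(
            observation=obs, consequence=consequence, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            metasvm=metasvm, cadd=cadd, revel=revel,
        )
        return [(v, VariantTruth(clazz, in_scope, bins, support))]

    def _observation(self, subject: SubjectRecord, g: int, ref: str, alt: str,
                     support: frozenset[str]) -> VariantObservation:
        return VariantObservation(
            subject_id=subject.subject_id, cohort=subject.cohort,
            cancer_type=subject.cancer_type, origin="germline",
            chromosome=self.model.chromosome, position=g + 1,
            ref=ref, alt=alt, callers=support, zygosity="het",
        )

    def _missense_scores(self, deleterious: bool):
        cfg = self.cfg
        if deleterious:
            while True:
                flags = (
                    self.rng.random() < cfg.p_metasvm_deleterious,
                    self.rng.random() < cfg.p_cadd_deleterious,
                    self.rng.random() < cfg.p_revel_deleterious,
                )
                if any(flags):
                    break
        else:
            flags = (False, False, False)
        metasvm = "Deleterious" if flags[0] else "Tolerated"
        cadd = float(self.rng.uniform(*(cfg.cadd_deleterious_range if flags[1]
                                        else cfg.cadd_benign_range)))
        revel = float(self.rng.uniform(*(cfg.revel_deleterious_range if flags[2]
                                         else cfg.revel_benign_range)))
        return metasvm, cadd, revel

    def _apply_missingness(self, metasvm, cadd, revel):
        miss = self.cfg.score_missingness
        if metasvm is not None and self.rng.random() < miss.get("metasvm", 0.0):
            metasvm = None
        if cadd is not None and self.rng.random() < miss.get("cadd", 0.0):
            cadd = None
        if revel is not None and self.rng.random() < miss.get("revel", 0.0):
            revel = None
        return metasvm, cadd, revel

    # -- cohort -----------------------------------------------------------
    def run(self):
        cfg = self.cfg
        types = sorted(cfg.cancer_type_weights)
        weights = np.array([cfg.cancer_type_weights[t] for t in types], dtype=float)
        weights /= weights.sum()
        subjects, variants = [], []
        truth = GroundTruth()
        for i in range(cfg.n_subjects):
            subject = SubjectRecord(
                subject_id=f"S{i:05d}",
                cohort="synthetic",
                cancer_type=str(self.rng.choice(types, p=weights)),
                sex=str(self.rng.choice(["Female", "Male"])),
                age_at_diagnosis=float(self.rng.integers(18, 90)),
                race="",
                vital_status="Living",
            )
            subjects.append(subject)
            used: set[int] = set()
            for bin_ in ("P", "LP", "VUS", "LB", "excluded"):
                if self.rng.random() >= cfg.bin_carrier_fractions.get(bin_, 0.0):
                    continue
                classes = BIN_CLASSES[bin_]
                probs = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
                probs /= probs.sum()
                clazz = str(self.rng.choice(classes, p=probs))
                for v, t in self._make_variant(subject, clazz, intent=bin_, used_positions=used):
                    variants.append(v)
                    truth.records[(subject.subject_id, _truth_key(v))] = t
            # caller false positives: single-caller benign calls, removed by
            # any >= 2-caller consensus
            for caller, fp in cfg.caller_false_call_rate.items():
                if self.rng.random() < fp:
                    for v, t in self._make_variant(subject, "synonymous", intent="LB",
                                                   used_positions=used):
                        v = replace(v, observation=replace(v.observation,
                                                           callers=frozenset({caller})))
                        variants.append(v)
                        truth.records[(subject.subject_id, _truth_key(v))] = replace(
                            t, callers=frozenset({caller})
                        )
        return variants, subjects, truth


def _truth_key(v: AnnotatedVariant) -> str:
    from .variants import variant_identity

    o = v.observation
    # disambiguate multi-allelic partners sharing an hgvs-less site
    return f"{variant_identity(v)}|{o.position}{o.ref}>{o.alt}"


def generate_cohort(
    config: SimulationConfig,
    model: TranscriptModel,
    registry: HotspotRegistry = DICER1_HOTSPOTS,
) -> tuple[list[AnnotatedVariant], list[SubjectRecord], GroundTruth]:
    """Generate an annotated cohort with ground truth.

    Returns ``(variants, subjects, truth)``.  Positions, splice distances
    and codons are derived from ``model``, so recomputing the geometry of
    any generated variant reproduces its intended class.
    """
    return _Generator(config, model, registry).run()


def degrade_annotations(
    variants: Sequence[AnnotatedVariant],
    noise_score_missingness: float = 0.0,
    noise_consequence: float = 0.0,
    seed: int = 0,
) -> list[AnnotatedVariant]:
    """Robustness harness: drop scores / perturb consequence labels.

    Each in-silico score is independently set missing with probability
    ``noise_score_missingness``; each variant's consequence label is
    swapped for a random different recognised label with probability
    ``noise_consequence``.  Ground truth objects are never touched.
    """
    for rate in (noise_score_missingness, noise_consequence):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("noise rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = ["missense", "stop_gained", "frameshift", "synonymous", "splice_region",
              "inframe_deletion"]
    out = []
    for v in variants:
        metasvm = None if (v.metasvm is not None and rng.random() < noise_score_missingness) else v.metasvm
        cadd = None if (v.cadd is not None and rng.random() < noise_score_missingness) else v.cadd
        revel = None if (v.revel is not None and rng.random() < noise_score_missingness) else v.revel
        consequence = v.consequence
        if rng.random() < noise_consequence:
            choices = [l for l in labels if l != consequence]
            consequence = str(rng.choice(choices))
        hgvs_p = v.hgvs_p
        if consequence == "stop_gained" and (hgvs_p is None or not hgvs_p.is_stop_gained):
            hgvs_p = ProteinChange("E", hgvs_p.residue if hgvs_p else 1, "*")
        out.append(
            AnnotatedVariant(
                observation=v.observation, consequence=consequence, hgvs_c=v.hgvs_c,
                hgvs_p=hgvs_p, metasvm=metasvm, cadd=cadd, revel=revel,
                pop_af=v.pop_af, kb_assertion=v.kb_assertion,
            )
        )
    return out


def caller_call_sets(
    variants: Sequence[AnnotatedVariant],
) -> dict[str, list[VariantObservation]]:
    """Rearrange observations into per-caller call sets for consensus merging."""
    sets: dict[str, list[VariantObservation]] = {}
    for v in variants:
        for caller in v.observation.callers:
            sets.setdefault(caller, []).append(v.observation)
    return sets
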