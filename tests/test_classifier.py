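"""The four-bin germline rule engine and the two-rule somatic call."""

from dataclasses import replace

import pytest

from dicerclass.classify import (
    CRITERIA,
    ClassificationError,
    KnowledgeBase,
    classify_germline,
    classify_somatic,
    tabulate_bins,
)
from dicerclass.hgvs import parse_hgvs_p
from dicerclass.variants import AnnotatedVariant, VariantObservation, variant_identity

ANY = CRITERIA["ANY"]


def make_missense(model, residue, metasvm=None, cadd=None, revel=None,
                  origin="germline", alt_aa="Cys"):
    g = model.genomic_of_c(3 * (residue - 1) + 2)
    return AnnotatedVariant(
        observation=VariantObservation(
            subject_id="S1", cohort="C", cancer_type="X", origin=origin,
            chromosome=model.chromosome, position=g + 1, ref="A", alt="G",
        ),
        consequence="missense",
        hgvs_p=parse_hgvs_p(f"p.Ala{residue}{alt_aa}"),
        metasvm=metasvm, cadd=cadd, revel=revel,
    )


def by_hgvs(tcga, text):
    for v in tcga.variants:
        if (v.hgvs_p is not None and str(v.hgvs_p) == text) or v.hgvs_c == text:
            return v
    raise KeyError(text)


class TestGermlineRules:
    def test_stop_gained_is_pathogenic_via_lof(self, tcga, model):
        res = classify_germline(by_hgvs(tcga, "p.Glu904*"), model, criterion=ANY)
        assert res.bin == "P" and "LOF" in res.rules_fired

    def test_canonical_splice_is_pathogenic(self, tcga, model):
        res = classify_germline(by_hgvs(tcga, "c.4206+1G>C"), model, criterion=ANY)
        assert res.bin == "P" and "canonical_splice" in res.rules_fired

    def test_hotspot_missense_is_pathogenic(self, tcga, model):
        res = classify_germline(by_hgvs(tcga, "p.Asp1810Asn"), model, criterion=ANY)
        assert res.bin == "P" and "hotspot" in res.rules_fired

    def test_deleterious_missense_is_likely_pathogenic(self, tcga, model):
        res = classify_germline(
            by_hgvs(tcga, "p.Ser1160Tyr"), model, criterion=CRITERIA["METASVM"]
        )
        assert res.bin == "LP" and res.rules_fired == ("missense_criterion",)

    def test_synonymous_is_likely_benign(self, model):
        g = model.genomic_of_c(300)
        v = AnnotatedVariant(
            observation=VariantObservation(
                subject_id="S1", cohort="C", cancer_type="X", origin="germline",
                chromosome=model.chromosome, position=g + 1, ref="A", alt="G",
            ),
            consequence="synonymous",
        )
        for crit in CRITERIA.values():
            assert classify_germline(v, model, criterion=crit).bin == "LB"

    def test_splice_region_is_vus(self, model):
        g = model.genomic_of_c(4206, 5)
        v = AnnotatedVariant(
            observation=VariantObservation(
                subject_id="S1", cohort="C", cancer_type="X", origin="germline",
                chromosome=model.chromosome, position=g + 1, ref="A", alt="G",
            ),
            consequence="splice_region",
        )
        assert classify_germline(v, model, criterion=ANY).bin == "VUS"

    @pytest.mark.parametrize(
        "cadd,expected", [(31.0, "LP"), (30.0, "LB"), (30.0001, "LP")]
    )
    def test_cadd_threshold_is_strict(self, model, cadd, expected):
        v = make_missense(model, 700, cadd=cadd)
        assert classify_germline(v, model, criterion=CRITERIA["CADD"]).bin == expected

    @pytest.mark.parametrize("revel,expected", [(0.76, "LP"), (0.75, "LB")])
    def test_revel_threshold_is_strict(self, model, revel, expected):
        v = make_missense(model, 700, revel=revel)
        assert classify_germline(v, model, criterion=CRITERIA["REVEL"]).bin == expected

    def test_missense_with_all_scores_missing_is_vus(self, model):
        v = make_missense(model, 700)
        for crit in CRITERIA.values():
            res = classify_germline(v, model, criterion=crit)
            assert res.bin == "VUS" and res.rules_fired == ("missense_scores_missing",)

    def test_criterion_relevance_restricts_to_its_own_score(self, model):
        # under the CADD criterion a missing CADD means unscorable, even
        # though metaSVM is present and Deleterious
        v = make_missense(model, 700, metasvm="Deleterious")
        assert classify_germline(v, model, criterion=CRITERIA["CADD"]).bin == "VUS"
        assert classify_germline(v, model, criterion=ANY).bin == "LP"

    def test_knowledge_base_hit_is_pathogenic(self, model):
        v = make_missense(model, 700, cadd=5.0)
        kb = KnowledgeBase.from_pairs([("p.Ala700Cys", "PMID:0000")])
        res = classify_germline(v, model, criterion=ANY, kb=kb)
        assert res.bin == "P" and "kb" in res.rules_fired

    def test_unusable_consequence_demands_reannotation(self, model):
        g = model.genomic_of_c(300)
        v = AnnotatedVariant(
            observation=VariantObservation(
                subject_id="S1", cohort="C", cancer_type="X", origin="germline",
                chromosome=model.chromosome, position=g + 1, ref="A", alt="G",
            ),
            consequence="other",
        )
        with pytest.raises(ClassificationError):
            classify_germline(v, model, criterion=ANY)


class TestInvariants:
    def test_determinism(self, tcga, model):
        for v in tcga.variants:
            a = classify_germline(v, model, criterion=ANY)
            b = classify_germline(v, model, criterion=ANY)
            assert a == b

    def test_p_dominance_deleting_scores_never_changes_p(self, tcga, model):
        for v in tcga.variants:
            before = classify_germline(v, model, criterion=ANY)
            stripped = replace(v, metasvm=None, cadd=None, revel=None)
            after = classify_germline(stripped, model, criterion=ANY)
            if before.bin == "P":
                assert after.bin == "P"
            else:
                # removing evidence can never upgrade a bin
                order = {"LB": 0, "VUS": 1, "LP": 2, "P": 3}
                assert order[after.bin] <= order[before.bin]

    def test_criterion_monotonicity(self, tcga, model):
        def lp_set(crit):
            return {
                variant_identity(v)
                for v in tcga.variants
                if classify_germline(v, model, criterion=CRITERIA[crit]).bin == "LP"
            }

        union = lp_set("ANY")
        for crit in ("METASVM", "CADD", "REVEL"):
            assert lp_set(crit) <= union

    def test_every_in_scope_variant_gets_exactly_one_bin(self, tcga, model):
        for v in tcga.variants:
            res = classify_germline(v, model, criterion=ANY)
            assert res.bin in ("P", "LP", "VUS", "LB")


class TestSomatic:
    def test_hotspot_somatic_is_pathogenic(self, tcga, model):
        hot = next(v for v in tcga.somatic_variants if v.hgvs_p.residue == 1709)
        assert classify_somatic(hot, model) == "pathogenic"

    def test_nonhotspot_somatic_missense_is_not_pathogenic(self, tcga, model):
        cold = next(v for v in tcga.somatic_variants if v.hgvs_p.residue == 937)
        assert classify_somatic(cold, model) == "not_pathogenic"

    def test_somatic_synonymous_not_pathogenic(self, model):
        g = model.genomic_of_c(333)
        v = AnnotatedVariant(
            observation=VariantObservation(
                subject_id="S1", cohort="C", cancer_type="X", origin="somatic",
                chromosome=model.chromosome, position=g + 1, ref="A", alt="G",
            ),
            consequence="synonymous",
        )
        assert classify_somatic(v, model) == "not_pathogenic"

    def test_somatic_canonical_splice_counts_as_lof(self, model):
        g = model.genomic_of_c(4206, 1)
        v = AnnotatedVariant(
            observation=VariantObservation(
                subject_id="S1", cohort="C", cancer_type="X", origin="somatic",
                chromosome=model.chromosome, position=g + 1, ref="C", alt="G",
            ),
            consequence="splice_donor", hgvs_c="c.4206+1G>C",
        )
        assert classify_somatic(v, model) == "pathogenic"


class TestTabulation:
    def test_pathogenic_block_of_the_carrier_roster(self, tcga, model):
        table = tabulate_bins(list(tcga.variants), model)
        p_block = table[(table.criterion == "METASVM") & (table.bin == "P")]
        assert dict(zip(p_block.category, p_block.n_unique)) == {
            "hotspot": 1, "stop_gained": 1, "splice_donor": 1,
        }

    def test_lp_counts_by_criterion(self, tcga, model):
        table = tabulate_bins(list(tcga.variants), model)
        lp = table[table.bin == "LP"].set_index("criterion")["n_unique"]
        assert lp["METASVM"] == 9 and lp["CADD"] == 5 and lp["REVEL"] == 1

    def test_p_and_vus_blocks_are_criterion_independent(self, tcga, model):
        table = tabulate_bins(list(tcga.variants), model)
        for bin_ in ("P", "VUS"):
            block = table[table.bin == bin_]
            per_crit = {
                c: dict(zip(g.category, g.n_unique))
                for c, g in block.groupby("criterion")
            }
            assert len({tuple(sorted(d.items())) for d in per_crit.values()}) <= 1

    def test_empty_input_gives_empty_table(self, model):
        assert tabulate_bins([], model).empty
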