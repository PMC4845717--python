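"""Outcome-classification rules: gene fit, patient categories, merging."""

import random

import pytest
from hypothesis import given, strategies as st

from irdx.outcomes import (
    GeneFit,
    GeneLookupError,
    classify_cohort,
    classify_patient,
    cohort_summary,
    gene_fit,
    merge_platforms,
)
from irdx.types import (
    DIAGNOSED,
    GeneModel,
    Inheritance,
    InheritanceMode,
    OutcomeCategory,
    Panel,
    Pathogenicity,
    PatientRecord,
    VariantCall,
    VariantClass,
    Zygosity,
)

CLEAR = Pathogenicity.CLEARLY_PATHOGENIC
LIKELY = Pathogenicity.LIKELY_PATHOGENIC


def _var(gene, pos, zyg, path, phase=None):
    return VariantCall(chrom="chr9", pos=pos, ref="A", alt="G", zygosity=zyg,
                       variant_class=VariantClass.SNV, pathogenicity=path,
                       gene=gene, phase=phase)


class TestGeneFit:
    def test_single_carrier_in_phenotype_mismatched_gene_is_none(self, models):
        """A nonsense carrier allele in a nonsyndromic-RP gene does not
        contribute to the diagnosis of a syndromic deaf-blind patient."""
        v = _var("IDH3B", 100, Zygosity.HET, LIKELY)
        assert gene_fit([v], models["IDH3B"], "usher") is GeneFit.NONE
        # ... but is a carrier state for an RP patient
        assert gene_fit([v], models["IDH3B"], "rp") is GeneFit.PARTIAL

    def test_compound_het_with_exon_deletion_is_full(self, models):
        intronic = _var("GPR98", 100, Zygosity.HET, LIKELY)
        exon_del = VariantCall(
            chrom="chr5", pos=90_109_981, ref="N", alt="<DEL>",
            zygosity=Zygosity.HET, variant_class=VariantClass.LARGE_DELETION,
            pathogenicity=LIKELY, gene="GPR98", end_pos=90_111_708)
        assert gene_fit([intronic, exon_del], models["GPR98"], "usher") is GeneFit.FULL

    def test_homozygous_recessive_is_full(self, models):
        v = _var("TRPM1", 100, Zygosity.HOM, LIKELY)
        assert gene_fit([v], models["TRPM1"], "other") is GeneFit.FULL

    def test_uncertain_variants_never_qualify(self, models):
        v = _var("USH2A", 100, Zygosity.HOM, Pathogenicity.UNCERTAIN)
        assert gene_fit([v], models["USH2A"], "usher") is GeneFit.NONE

    def test_cis_phased_pair_is_not_compound_het(self, models):
        a = _var("USH2A", 100, Zygosity.HET, CLEAR, phase="hapA")
        b = _var("USH2A", 200, Zygosity.HET, CLEAR, phase="hapA")
        assert gene_fit([a, b], models["USH2A"], "usher") is GeneFit.PARTIAL
        # unphased pair assumed in trans
        c = _var("USH2A", 200, Zygosity.HET, CLEAR)
        assert gene_fit([a, c], models["USH2A"], "usher") is GeneFit.FULL

    def test_male_het_coded_xlr_call_is_diagnostic(self, models):
        v = _var("RPGR", 100, Zygosity.HET, CLEAR)
        assert gene_fit([v], models["RPGR"], "rp", sex="male") is GeneFit.FULL
        # unknown sex requires explicit hom/hemi coding
        assert gene_fit([v], models["RPGR"], "rp") is GeneFit.PARTIAL


class TestClassifyPatient:
    def test_diagnosis_in_one_gene_retains_carrier_finding_in_another(self, models):
        """A recessive diagnosis plus a single het deletion in an unrelated
        recessive gene: diagnosed, with the deletion kept as a carrier
        finding."""
        eys = [_var("EYS", 100, Zygosity.HET, CLEAR),
               _var("EYS", 200, Zygosity.HET, LIKELY)]
        rpgrip1_del = VariantCall(
            chrom="chr14", pos=21_794_817, ref="N", alt="<DEL>",
            zygosity=Zygosity.HET, variant_class=VariantClass.LARGE_DELETION,
            pathogenicity=LIKELY, gene="RPGRIP1", end_pos=21_799_356)
        rec = PatientRecord("067429", "rp", variants_ngs=eys + [rpgrip1_del])
        category, diagnosis = classify_patient(rec, models, "ngs")
        assert category is OutcomeCategory.DIAGNOSED_CONFIRMED
        assert diagnosis.gene == "EYS"
        assert diagnosis.mode is InheritanceMode.AR_COMPHET
        assert [v.gene for v in diagnosis.carrier_findings] == ["RPGRIP1"]

    def test_no_variants_is_undiagnosed(self, models):
        rec = PatientRecord("p", "rp")
        category, diagnosis = classify_patient(rec, models, "ngs")
        assert category is OutcomeCategory.UNDIAGNOSED and diagnosis is None

    def test_rezygosed_missense_in_trans_with_deletion_refines_diagnosis(self, models):
        """Homozygous missense re-called het plus a het exon deletion:
        the diagnosis survives, switching from hom to compound het."""
        mis_hom = _var("USH2A", 100, Zygosity.HOM, LIKELY)
        rec = PatientRecord("12008422", "usher", variants_ngs=[mis_hom])
        cat_ngs, diag_ngs = classify_patient(rec, models, "ngs")
        assert cat_ngs in DIAGNOSED and diag_ngs.mode is InheritanceMode.AR_HOM
        rec.variants_wgs = [
            mis_hom.with_(platform="wgs", zygosity=Zygosity.HET),
            VariantCall(chrom="chr1", pos=216_167_537, ref="N", alt="<DEL>",
                        zygosity=Zygosity.HET, platform="wgs",
                        variant_class=VariantClass.LARGE_DELETION,
                        pathogenicity=LIKELY, gene="USH2A", end_pos=216_177_486),
        ]
        merged = merge_platforms(rec)
        assert [v.zygosity for v in merged.variants_wgs] == [Zygosity.HET,
                                                             Zygosity.HET]
        cat, diag = classify_patient(merged, models, "merged")
        assert cat in DIAGNOSED and diag.mode is InheritanceMode.AR_COMPHET

    def test_unknown_gene_raises(self, models):
        rec = PatientRecord("p", "rp", variants_ngs=[_var("NOTAGENE", 1,
                                                          Zygosity.HET, CLEAR)])
        with pytest.raises(GeneLookupError, match="NOTAGENE"):
            classify_patient(rec, models, "ngs")

    def test_confirmed_requires_a_clearly_pathogenic_allele(self, models):
        hom_likely = _var("USH2A", 100, Zygosity.HOM, LIKELY)
        rec = PatientRecord("p", "usher", variants_ngs=[hom_likely])
        category, _ = classify_patient(rec, models, "ngs")
        assert category is OutcomeCategory.DIAGNOSED_PROVISIONAL
        rec2 = PatientRecord("q", "usher",
                             variants_ngs=[_var("USH2A", 100, Zygosity.HOM, CLEAR)])
        category2, _ = classify_patient(rec2, models, "ngs")
        assert category2 is OutcomeCategory.DIAGNOSED_CONFIRMED

    @given(st.randoms(use_true_random=False))
    def test_variant_order_never_changes_outcome(self, models, rnd):
        variants = [
            _var("USH2A", 100, Zygosity.HET, CLEAR),
            _var("USH2A", 200, Zygosity.HET, LIKELY),
            _var("IDH3B", 300, Zygosity.HET, LIKELY),
            _var("ABCA4", 400, Zygosity.HET, CLEAR),
        ]
        rec = PatientRecord("p", "usher", variants_ngs=list(variants))
        baseline = classify_patient(rec, models, "ngs")
        shuffled = list(variants)
        rnd.shuffle(shuffled)
        rec2 = PatientRecord("p", "usher", variants_ngs=shuffled)
        result = classify_patient(rec2, models, "ngs")
        assert result[0] is baseline[0]
        assert result[1].gene == baseline[1].gene
        assert result[1].mode is baseline[1].mode

    def test_adding_pathogenic_variant_never_undiagnoses(self, models):
        """Monotonicity: extending a diagnosed patient's variant list with a
        clearly pathogenic allele cannot remove the diagnosis."""
        base = [_var("USH2A", 100, Zygosity.HOM, CLEAR)]
        rec = PatientRecord("p", "usher", variants_ngs=base)
        assert classify_patient(rec, models, "ngs")[0] in DIAGNOSED
        for extra_gene, pos in (("GPR98", 500), ("IDH3B", 600), ("ABCA4", 700)):
            rec2 = PatientRecord("p", "usher",
                                 variants_ngs=base + [_var(extra_gene, pos,
                                                           Zygosity.HET, CLEAR)])
            assert classify_patient(rec2, models, "ngs")[0] in DIAGNOSED


class TestMergePlatforms:
    def test_union_collapses_duplicates(self, models):
        a = _var("USH2A", 100, Zygosity.HET, CLEAR)
        rec = PatientRecord("p", "usher", variants_ngs=[a],
                            variants_wgs=[a.with_(platform="wgs"),
                                          _var("USH2A", 200, Zygosity.HET, LIKELY)])
        merged = merge_platforms(rec)
        assert len(merged.variants_wgs) == 2

    def test_identical_sets_identity(self):
        a = _var("USH2A", 100, Zygosity.HET, CLEAR)
        rec = PatientRecord("p", "usher", variants_ngs=[a], variants_wgs=[a])
        assert merge_platforms(rec).variants_wgs == [a]

    def test_idempotent(self, fx):
        for rec in fx.subsample():
            once = merge_platforms(rec)
            twice = merge_platforms(once)
            assert twice.variants_wgs == once.variants_wgs


class TestCohortSummary:
    def test_categories_partition_cohort(self, fx, classified_ngs):
        summary = cohort_summary(classified_ngs, fx.gene_models)
        assert sum(summary.category_counts.values()) == summary.n == 562

    def test_all_undiagnosed_cohort_has_zero_yield(self, models):
        records = [PatientRecord(f"p{i}", "rp") for i in range(10)]
        summary = cohort_summary(classify_cohort(records, models, "ngs"), models)
        assert summary.yield_percent == 0
        assert summary.diagnosed == 0
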