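"""Variant normalization, identity, differencing, and categorization."""

import pytest
from hypothesis import given, strategies as st

from irdx.diffing import (
    CategorizationError,
    DiffCategory,
    NormalizationError,
    ReferenceContext,
    categorize,
    category_counts,
    diff_callsets,
    diff_cohort,
    normalize,
    reciprocal_overlap,
    same_variant,
)
from irdx.types import (
    Pathogenicity,
    RegionClass,
    VariantCall,
    VariantClass,
    Zygosity,
)

LIKELY = Pathogenicity.LIKELY_PATHOGENIC

# 10-bp context GCATTTTGCA: deleting one T from the T-run has many encodings
CONTEXT = ReferenceContext({"chrT": (1, "GCATTTTGCA")})
CANONICAL = ("chrT", 3, "AT", "A")


def _iv(pos, ref, alt, vclass=None):
    if vclass is None:
        vclass = VariantClass.SNV if len(ref) == len(alt) == 1 else VariantClass.INDEL
    return VariantCall(chrom="chrT", pos=pos, ref=ref, alt=alt,
                       zygosity=Zygosity.HET, variant_class=vclass,
                       pathogenicity=LIKELY, gene="G1")


def _deletion(chrom, pos, end, gene="G1"):
    return VariantCall(chrom=chrom, pos=pos, ref="N", alt="<DEL>",
                       zygosity=Zygosity.HET,
                       variant_class=VariantClass.LARGE_DELETION,
                       pathogenicity=LIKELY, gene=gene, end_pos=end)


class TestNormalize:
    # every equivalent encoding of the same single-T deletion in the context
    ENCODINGS = [
        (3, "AT", "A"), (4, "TT", "T"), (5, "TT", "T"), (6, "TT", "T"),
        (4, "T", ""), (5, "T", ""), (6, "T", ""), (7, "T", ""),
        (3, "ATT", "AT"), (3, "ATTT", "ATT"), (4, "TTT", "TT"),
        (4, "TTTT", "TTT"), (3, "ATTTT", "ATTT"),
    ]

    @pytest.mark.parametrize("pos,ref,alt", ENCODINGS)
    def test_all_encodings_converge(self, pos, ref, alt):
        v = normalize(_iv(pos, ref, alt), CONTEXT)
        assert (v.chrom, v.pos, v.ref, v.alt) == CANONICAL

    def test_snv_unchanged(self):
        v = _iv(5, "T", "G")
        assert normalize(v, CONTEXT) is v
        assert normalize(v) is v

    @pytest.mark.parametrize("pos,ref,alt", ENCODINGS)
    def test_idempotent(self, pos, ref, alt):
        once = normalize(_iv(pos, ref, alt), CONTEXT)
        assert normalize(once, CONTEXT) == once

    def test_null_variant_raises(self):
        with pytest.raises(NormalizationError, match="null"):
            normalize(_iv(4, "TT", "TT", VariantClass.COMPLEX_INDEL), CONTEXT)

    def test_empty_allele_without_reference_raises(self):
        with pytest.raises(NormalizationError, match="reference"):
            normalize(_iv(5, "T", ""))

    def test_no_reference_mode_trims_conservatively(self):
        # shared prefix removed; no left shift attempted without a reference
        v = normalize(_iv(4, "TCGA", "TCG"))
        assert (v.pos, v.ref, v.alt) == (6, "GA", "G")

    @given(st.integers(3, 6), st.integers(1, 3))
    def test_idempotence_property(self, pos, length):
        ref = CONTEXT._snippets["chrT"][1][pos - 1: pos - 1 + length + 1]
        alt = ref[:1]
        v = _iv(pos, ref, alt, VariantClass.INDEL)
        once = normalize(v, CONTEXT)
        assert normalize(once, CONTEXT) == once


class TestSameVariant:
    def test_identical_snvs(self):
        assert same_variant(_iv(5, "T", "G"), _iv(5, "T", "G"))

    def test_different_positions(self):
        assert not same_variant(_iv(5, "T", "G"), _iv(6, "T", "G"))

    def test_deletion_breakpoint_tolerance(self):
        """Two calls of the same exon deletion with breakpoints 50 bp apart
        match at the default reciprocal-overlap threshold."""
        a = _deletion("chr5", 90_109_981, 90_111_708)
        b = _deletion("chr5", 90_110_031, 90_111_758)
        # interval-overlap arithmetic: shared / span = 1678 / 1728
        assert reciprocal_overlap(a, b) == pytest.approx(1678 / 1728)
        assert same_variant(a, b)
        assert not same_variant(a, b, overlap_threshold=0.99)

    def test_deletions_on_different_chromosomes(self):
        a = _deletion("chr5", 100, 2000)
        b = _deletion("chr6", 100, 2000)
        assert not same_variant(a, b)

    def test_deletion_never_matches_sequence_variant(self):
        assert not same_variant(_deletion("chrT", 5, 100), _iv(5, "T", "G"))


class TestDiffCallsets:
    def test_diff_self_is_empty(self, fx, models):
        for rec in fx.subsample():
            assert diff_callsets(rec.variants_wgs, rec.variants_wgs, models,
                                 known_miss=fx.known_miss) == []

    def test_diff_against_empty_returns_all_relevant(self, models, fx):
        calls = [v for _, v in fx.table9]
        records = diff_callsets(calls, [], models, known_miss=fx.known_miss)
        assert len(records) == len(calls)

    def test_partition_of_relevant_set(self, models, fx):
        """|diff| + |matched| = |relevant| for each subsample patient."""
        from irdx.diffing import relevance_filter

        for rec in fx.subsample():
            diffs = diff_callsets(rec.variants_wgs, rec.variants_ngs, models,
                                  known_miss=fx.known_miss)
            relevant = [v for v in rec.variants_wgs if relevance_filter(v)]
            matched = [
                v for v in relevant
                if any(same_variant(v, o) for o in rec.variants_ngs)
            ]
            assert len(diffs) + len(matched) == len(relevant)

    def test_encoding_invariance(self, models):
        """Re-encoding an indel does not change the diff output."""
        canonical = _iv(3, "AT", "A", VariantClass.INDEL)
        for pos, ref, alt in [(4, "TT", "T"), (6, "TT", "T"), (4, "TTTT", "TTT")]:
            alt_encoding = _iv(pos, ref, alt, VariantClass.INDEL)
            records = diff_callsets([alt_encoding], [canonical], models,
                                    reference=CONTEXT)
            assert records == []

    def test_fixture_diff_grouping(self, fx, models):
        from irdx.outcomes import merge_platforms

        merged = [merge_platforms(r) for r in fx.subsample()]
        records = diff_cohort(merged, models, fx.known_miss)
        assert len(records) == 14
        assert category_counts(records) == {
            "large_deletion": 5,
            "intronic_variant": 3,
            "insertion_deletion": 3,
            "informatics_miss": 2,
            "additional_gene_variant": 1,
        }

    def test_deterministic_order(self, fx, models):
        merged = list(reversed(fx.subsample()))
        records = diff_cohort(merged, models, fx.known_miss)
        keys = [(r.variant.chrom, r.variant.pos, r.patient_id) for r in records]
        assert keys == sorted(keys)


class TestCategorize:
    def test_large_deletion_takes_precedence(self, models, fx):
        v = _deletion("chr2", 112_648_150, 112_739_206, gene="MERTK")
        assert categorize(v, models["MERTK"], fx.known_miss) \
            is DiffCategory.LARGE_DELETION

    def test_second_tier_gene_is_additional(self, models, fx):
        v = VariantCall(chrom="chr15", pos=31_358_296, ref="A", alt="G",
                        zygosity=Zygosity.HOM, variant_class=VariantClass.SNV,
                        pathogenicity=LIKELY, gene="TRPM1", cdna="c.707T>C")
        assert categorize(v, models["TRPM1"], fx.known_miss) \
            is DiffCategory.ADDITIONAL_GENE_VARIANT

    def test_known_miss_list_beats_region_class(self, models, fx):
        """The two recurrent splice-region alleles on the known-miss list are
        informatics errors even though their region class is intronic."""
        v = VariantCall(chrom="chr1", pos=94_476_351, ref="G", alt="A",
                        zygosity=Zygosity.HET, variant_class=VariantClass.SNV,
                        region_class=RegionClass.INTRONIC,
                        pathogenicity=LIKELY, gene="ABCA4", cdna="c.5714+5G>A")
        assert categorize(v, models["ABCA4"], fx.known_miss) \
            is DiffCategory.INFORMATICS_MISS
        off_list = v.with_(pos=94_476_951, ref="T", alt="C", cdna="c.5461-10T>C")
        assert categorize(off_list, models["ABCA4"], fx.known_miss) \
            is DiffCategory.INTRONIC_VARIANT

    def test_coding_indel_is_insertion_deletion(self, models, fx):
        v = VariantCall(chrom="chr19", pos=48_342_972, ref="AC", alt="A",
                        zygosity=Zygosity.HET, variant_class=VariantClass.INDEL,
                        pathogenicity=LIKELY, gene="CRX", cdna="c.648delC")
        assert categorize(v, models["CRX"], fx.known_miss) \
            is DiffCategory.INSERTION_DELETION

    def test_unannotated_variant_raises(self, models, fx):
        v = VariantCall(chrom="chr1", pos=10, ref="A", alt="G",
                        zygosity=Zygosity.HET, variant_class=VariantClass.SNV,
                        pathogenicity=LIKELY)
        with pytest.raises(CategorizationError, match="gene annotation"):
            categorize(v, None, fx.known_miss)
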