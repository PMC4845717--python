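"""Concordance scoring, brute-force equivalence, adjudication arithmetic."""

import random

import pytest
from hypothesis import given, strategies as st

from irdx.concordance import (
    AdjudicationRecord,
    ConcordanceTable,
    Discordance,
    Resolution,
    adjust_with_adjudication,
    build_table,
    classify_site,
    index_calls,
    restrict_sites,
)
from irdx.types import (
    GenomicInterval,
    GenotypeClass,
    GenotypeSite,
    IrdxError,
    VariantCall,
    VariantClass,
    Zygosity,
)


def _site(pos, gclass, alt="G"):
    return GenotypeSite("chr1", pos, "A", alt if gclass != GenotypeClass.HOM_REF else None,
                        gclass)


def _call(pos, zyg=Zygosity.HET, alt="G"):
    return VariantCall(chrom="chr1", pos=pos, ref="A", alt=alt, zygosity=zyg,
                       variant_class=VariantClass.SNV, platform="p")


class TestRestrictSites:
    def test_boundary_semantics(self):
        regions = [GenomicInterval("chr1", 100, 200)]  # 1-based 101..200
        inside = _site(150, GenotypeClass.HET)
        on_end = _site(200, GenotypeClass.HET)
        past_end = _site(201, GenotypeClass.HET)
        at_start = _site(100, GenotypeClass.HET)
        kept = restrict_sites([inside, on_end, past_end, at_start], regions)
        assert kept == [inside, on_end]

    def test_fixture_sites_all_inside_design(self, fx):
        kept = restrict_sites(fx.truth_wgs, fx.concordance_regions)
        assert len(kept) == len(fx.truth_wgs) == 928 + 3238


# every (truth genotype, pipeline call) pairing, enumerated by hand
CASES = [
    # truth hom_ref
    (GenotypeClass.HOM_REF, None, "tn", "tn"),
    (GenotypeClass.HOM_REF, Zygosity.HET, "fp", "fp"),
    (GenotypeClass.HOM_REF, Zygosity.HOM, "fp", "fp"),
    # truth het
    (GenotypeClass.HET, None, "fn", "fn"),
    (GenotypeClass.HET, Zygosity.HET, "tp", "tp"),
    (GenotypeClass.HET, Zygosity.HOM, "tp", "fn"),  # zygosity mismatch
    # truth hom_alt
    (GenotypeClass.HOM_ALT, None, "fn", "fn"),
    (GenotypeClass.HOM_ALT, Zygosity.HOM, "tp", "tp"),
    (GenotypeClass.HOM_ALT, Zygosity.HET, "tp", "fn"),  # zygosity mismatch
]


class TestClassifySite:
    @pytest.mark.parametrize("truth_class,call_zyg,lenient,strict", CASES)
    def test_genotype_pair_table(self, truth_class, call_zyg, lenient, strict):
        truth = _site(10, truth_class)
        calls = [] if call_zyg is None else [_call(10, call_zyg)]
        index = index_calls(calls)
        cell, _ = classify_site(truth, index)
        assert cell == lenient
        cell_strict, _ = classify_site(truth, index, genotype_strict=True)
        assert cell_strict == strict

    def test_allele_mismatch_is_fn(self):
        truth = _site(10, GenotypeClass.HET, alt="G")
        cell, disc = classify_site(truth, index_calls([_call(10, alt="T")]))
        assert cell == "fn" and disc is not None

    def test_zygosity_mismatch_recorded_but_scored_tp(self):
        truth = _site(10, GenotypeClass.HET)
        cell, disc = classify_site(truth, index_calls([_call(10, Zygosity.HOM)]))
        assert cell == "tp"
        assert disc is not None and disc.cell == "zygosity"


def _random_instance(rng, n):
    truth, calls = [], []
    for i in range(n):
        pos = 100 + 3 * i
        r = rng.random()
        if r < 0.5:
            truth.append(_site(pos, GenotypeClass.HOM_REF))
            if rng.random() < 0.1:
                calls.append(_call(pos))
        else:
            gclass = GenotypeClass.HET if r < 0.75 else GenotypeClass.HOM_ALT
            truth.append(_site(pos, gclass))
            if rng.random() < 0.9:
                zyg = Zygosity.HET if rng.random() < 0.5 else Zygosity.HOM
                alt = "G" if rng.random() < 0.9 else "T"
                calls.append(_call(pos, zyg, alt))
    return truth, calls


class TestBuildTable:
    def test_matches_naive_double_loop(self):
        """build_table equals a per-site brute force on random instances."""
        rng = random.Random(20)
        for _ in range(10):
            truth, calls = _random_instance(rng, rng.randint(1, 200))
            table = build_table(truth, calls)
            # naive O(sites x calls) recount
            naive = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
            for s in truth:
                at_pos = [c for c in calls if (c.chrom, c.pos) == (s.chrom, s.pos)]
                if s.genotype_class is GenotypeClass.HOM_REF:
                    naive["fp" if at_pos else "tn"] += 1
                else:
                    naive["tp" if any(c.alt == s.alt_allele for c in at_pos)
                          else "fn"] += 1
            assert (table.tp, table.fn, table.tn, table.fp) == (
                naive["tp"], naive["fn"], naive["tn"], naive["fp"])

    def test_order_independence(self):
        rng = random.Random(7)
        truth, calls = _random_instance(rng, 150)
        a = build_table(truth, calls)
        shuffled_truth, shuffled_calls = truth[:], calls[:]
        rng.shuffle(shuffled_truth)
        rng.shuffle(shuffled_calls)
        b = build_table(shuffled_truth, shuffled_calls)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)

    def test_empty_truth_flags_metrics_undefined(self):
        table = build_table([], [])
        assert table.sensitivity is None and table.specificity is None
        rep = table.to_report()
        assert rep["sensitivity_defined"] is False
        assert rep["sensitivity_pct"] is None

    def test_fixture_worked_examples(self, fx):
        ngs = build_table(fx.truth_ngs, fx.calls_ngs, fx.concordance_regions)
        assert (ngs.n_snv, ngs.n_homref, ngs.fp) == (616, 2098, 0)
        assert ngs.to_report()["sensitivity_pct"] == 100.0
        assert ngs.to_report()["specificity_pct"] == 100.0
        wgs = build_table(fx.truth_wgs, fx.calls_wgs, fx.concordance_regions)
        assert (wgs.n_snv, wgs.n_homref, wgs.fp) == (928, 3238, 3)
        assert wgs.to_report()["sensitivity_pct"] == 100.0
        assert wgs.to_report()["specificity_pct"] == 99.9


def _table_with_discordances(n_fn, n_fp):
    discs = [Discordance("chr1", 10 + i, GenotypeClass.HET, None, "fn")
             for i in range(n_fn)]
    discs += [Discordance("chr1", 10_000 + i, GenotypeClass.HOM_REF,
                          Zygosity.HET, "fp") for i in range(n_fp)]
    return ConcordanceTable(tp=100, fn=n_fn, tn=500, fp=n_fp,
                            discordant_sites=discs)


def _adjudicate(table, n_pipeline_correct, n_unresolved):
    records = []
    for i, d in enumerate(table.discordant_sites):
        if i < n_pipeline_correct:
            res = Resolution.PIPELINE_CORRECT
        elif i < n_pipeline_correct + n_unresolved:
            res = Resolution.UNRESOLVED
        else:
            res = Resolution.TRUTH_CORRECT
        records.append(AdjudicationRecord(d.site, None, d.truth_genotype.value, res))
    return records


class TestAdjudication:
    def test_spreadsheet_recount(self):
        """1000 adjudicated discordances, 21 pipeline-correct, 6 unresolved."""
        table = _table_with_discordances(n_fn=600, n_fp=400)
        records = _adjudicate(table, n_pipeline_correct=21, n_unresolved=6)
        adj = adjust_with_adjudication(table, records)
        assert adj.truth_error_rate == pytest.approx(0.021)
        # the first 21 discordances are fn sites -> all 21 move fn -> tp
        assert adj.adjusted.tp == 121 and adj.adjusted.fn == 579
        assert adj.adjusted.tn == 500 and adj.adjusted.fp == 400

    def test_all_truth_wrong_degenerate(self):
        table = _table_with_discordances(n_fn=2, n_fp=0)
        records = _adjudicate(table, n_pipeline_correct=2, n_unresolved=0)
        adj = adjust_with_adjudication(table, records)
        assert adj.truth_error_rate == 1.0
        assert adj.adjusted.fn == 0
        assert adj.adj_sensitivity == 1.0

    def test_no_discordances_identity(self):
        table = ConcordanceTable(tp=10, fn=0, tn=20, fp=0)
        adj = adjust_with_adjudication(table, [])
        assert adj.truth_error_rate is None
        assert (adj.adjusted.tp, adj.adjusted.fn) == (10, 0)

    def test_record_for_concordant_site_raises(self):
        table = ConcordanceTable(tp=10, fn=0, tn=20, fp=0)
        rec = AdjudicationRecord(("chr1", 999), None, "het",
                                 Resolution.PIPELINE_CORRECT)
        with pytest.raises(IrdxError, match="discordant"):
            adjust_with_adjudication(table, [rec])

    @given(
        n_fn=st.integers(0, 50),
        n_fp=st.integers(0, 50),
        n_correct=st.integers(0, 100),
        n_unresolved=st.integers(0, 100),
    )
    def test_count_conservation_and_monotonicity(self, n_fn, n_fp, n_correct,
                                                 n_unresolved):
        """Row totals are invariant under reclassification, and resolving a
        discordance for the pipeline never lowers either metric."""
        table = _table_with_discordances(n_fn, n_fp)
        n_disc = len(table.discordant_sites)
        n_correct = min(n_correct, n_disc)
        n_unresolved = min(n_unresolved, n_disc - n_correct)
        adj = adjust_with_adjudication(table, _adjudicate(table, n_correct,
                                                          n_unresolved))
        assert adj.adjusted.n_snv == table.n_snv
        assert adj.adjusted.n_homref == table.n_homref
        if table.sensitivity is not None:
            assert adj.adj_sensitivity >= table.sensitivity
        if table.specificity is not None:
            assert adj.adj_specificity >= table.specificity
        if n_correct + 1 <= n_disc:
            more = adjust_with_adjudication(
                table, _adjudicate(table, n_correct + 1, max(0, n_unresolved - 1)))
            assert more.adj_sensitivity >= adj.adj_sensitivity
            assert more.adj_specificity >= adj.adj_specificity
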