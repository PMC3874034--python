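"""Contingency tests, enrichment measures and the summary table."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import fisher_two_sided_bruteforce
from stmaburden import (
    ContingencyTable2x2,
    EnrichmentReport,
    TestMethod,
    association_enrichment,
    build_table1,
    chi2_yates_p,
    contingency_test,
    fisher_exact_p,
    fold_vs_control,
    merge_maximal,
    map_genes,
    stma_metrics,
)
from stmaburden.regions import GeneAnnotation, GenomicInterval

# reference p-values computed with R 4.3.3 chisq.test(correct=TRUE) / fisher.test
R_CHISQ = {
    (14, 852, 9, 2772): 7.766121099569e-05,
    (40, 29, 9, 431): 3.657967606495e-47,
}
R_FISHER = {
    (2, 83, 9, 2772): 4.018761073072e-02,
    (5, 12, 7, 3): 5.675057208238e-02,
    (3, 1, 1, 3): 4.857142857143e-01,
    (8, 2, 1, 5): 3.496503496503e-02,
    (0, 7, 3, 9): 2.631578947368e-01,
    (12, 45, 30, 102): 8.510648461886e-01,
}


class TestChi2Yates:
    @pytest.mark.parametrize("table,expected", sorted(R_CHISQ.items()))
    def test_matches_r(self, table, expected):
        assert chi2_yates_p(ContingencyTable2x2(*table)) == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_on_large_tables(self, rng):
        for _ in range(50):
            t = tuple(int(x) for x in rng.integers(20, 500, size=4))
            ours = chi2_yates_p(ContingencyTable2x2(*t))
            ref = sps.chi2_contingency([[t[0], t[1]], [t[2], t[3]]], correction=True).pvalue
            # identical unless |O-E| < 0.5, where the capped correction gives
            # stat 0 and scipy clips the corrected deviation to 0 as well
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_correction_capped_at_deviation(self):
        # tiny departure from independence: the capped Yates term zeroes the
        # statistic instead of overshooting into a spurious signal
        p = chi2_yates_p(ContingencyTable2x2(10, 10, 10, 11))
        assert p == pytest.approx(1.0)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", sorted(R_FISHER.items()))
    def test_matches_r(self, table, expected):
        assert fisher_exact_p(ContingencyTable2x2(*table)) == pytest.approx(expected, rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_p(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_bruteforce_enumeration(self, a, b, c, d):
        """Exact agreement (1e-10) with log-factorial enumeration, margins <= 60."""
        if a + b == 0 or c + d == 0:
            return
        ours = fisher_exact_p(ContingencyTable2x2(a, b, c, d))
        assert ours == pytest.approx(fisher_two_sided_bruteforce(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b == 0 or c + d == 0:
                continue
            ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_exact_p(ContingencyTable2x2(a, b, c, d)) == pytest.approx(
                ref, rel=1e-8
            )


class TestContingencyTest:
    def test_fisher_triggered_by_small_expected_cell(self):
        # expected StMA count in the test set is 0.33 << 5
        res = contingency_test(ContingencyTable2x2(2, 83, 9, 2772))
        assert res.method is TestMethod.FISHER_EXACT
        assert res.p_value == pytest.approx(0.0402, abs=5e-5)

    def test_chi2_when_all_expected_at_least_five(self):
        res = contingency_test(ContingencyTable2x2(14, 852, 9, 2772))
        assert res.method is TestMethod.CHI2_YATES

    def test_selection_rule_matches_expected_matrix(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if a + b == 0 or c + d == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            res = contingency_test(t)
            obs = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            want_fisher = (expected < 5).any()
            assert (res.method is TestMethod.FISHER_EXACT) == want_fisher

    def test_fold_from_raw_counts(self):
        res = contingency_test(ContingencyTable2x2(14, 852, 9, 2772))
        assert res.fold_enrichment == pytest.approx((14 / 866) / (9 / 2781))
        assert round(res.fold_enrichment) == 5  # the reported full-precision fold
        res_sz = contingency_test(ContingencyTable2x2(2, 83, 9, 2772))
        assert res_sz.fold_enrichment == pytest.approx(7.27, abs=0.005)

    def test_enrichment_p_monotone_in_a(self):
        """More StMA hits (b, c, d fixed) never weakens the enrichment signal."""
        for b, c, d in [(50, 5, 100), (20, 10, 40), (200, 9, 2772)]:
            base_rate = c / (c + d)
            prev = None
            for a in range(0, 30):
                if a / (a + b) < base_rate:
                    continue  # only the enrichment side of the alternative
                n = a + b + c + d
                one_sided = float(sps.hypergeom.sf(a - 1, n, a + c, a + b))
                if prev is not None:
                    assert one_sided <= prev + 1e-12
                prev = one_sided

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 5, 5)


class TestAssociationEnrichment:
    def test_expected_hits_proportional_to_list_sizes(self):
        stma = {f"s{i}" for i in range(30)}
        ba = {f"b{i}" for i in range(70)}
        candidates = {"s0", "s1", "b0", "b1", "b2", "b3", "x"}
        res = association_enrichment(candidates, stma, ba)
        assert (res.observed_stma, res.observed_ba) == (2, 4)
        assert res.expected_stma == pytest.approx(6 * 30 / 100)
        assert res.fold == pytest.approx(2 / 1.8)
        assert res.test is not None

    def test_published_fold_arithmetic(self):
        # observed/expected pairs reported for GWAS candidate lists
        assert 2 / 0.6 == pytest.approx(3.33, abs=0.005)
        assert 3 / 1.54 == pytest.approx(1.95, abs=0.005)

    def test_no_hits(self):
        res = association_enrichment({"z"}, {"s"}, {"b"})
        assert res.fold is None and res.test is None

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            association_enrichment(set(), {"g"}, {"g"})


def _toy_dataset():
    """Five CNV regions, hand-checkable by eye."""
    cnvs = [
        GenomicInterval("chr1", 0, 1_000_000),
        GenomicInterval("chr1", 2_000_000, 3_000_000),
        GenomicInterval("chr1", 2_500_000, 4_000_000),  # merges with previous
        GenomicInterval("chr2", 0, 500_000),
        GenomicInterval("chr2", 1_000_000, 2_000_000),
        GenomicInterval("chr3", 0, 500_000),
    ]
    genes = [
        GeneAnnotation("g1", GenomicInterval("chr1", 100, 10_100)),
        GeneAnnotation("g2", GenomicInterval("chr1", 2_600_000, 2_610_000)),
        GeneAnnotation("g3", GenomicInterval("chr2", 100_000, 110_000)),
        GeneAnnotation("g4", GenomicInterval("chr2", 1_500_000, 1_510_000)),
        GeneAnnotation("g5", GenomicInterval("chr3", 600_000, 610_000)),  # outside
    ]
    regions = merge_maximal(cnvs)
    map_genes(regions, genes)
    return regions


class TestMetricsAndTable:
    def test_stma_metrics_hand_computed(self):
        regions = _toy_dataset()  # 5 merged regions, 5.0 Mb total, genes g1..g4
        report = stma_metrics("toy", {"g1", "g2", "g3", "g4"}, {"g1", "g3"}, regions)
        assert report.total_genes == 4 and report.stma_genes == 2
        assert report.n_regions == 5
        assert report.total_mb == pytest.approx(5.0)
        assert report.stma_per_1000 == pytest.approx(500.0)
        assert report.stma_per_mb == pytest.approx(2 / 5.0)
        # regions with an StMA gene: chr1:0-1M (g1) and chr2:0-0.5M (g3)
        assert report.n_regions_with_stma == 2
        assert report.pct_regions_with_stma == pytest.approx(40.0)
        assert report.genes_per_mb == pytest.approx(4 / 5.0)

    def test_fold_vs_control_self_is_unity(self):
        regions = _toy_dataset()
        report = stma_metrics("toy", {"g1", "g2", "g3", "g4"}, {"g1"}, regions)
        out = fold_vs_control(report, report)
        assert out.fold_per_1000_vs_control == 1.0
        assert out.fold_per_mb_vs_control == 1.0

    def test_zero_stma_everywhere(self):
        regions = _toy_dataset()
        report = stma_metrics("toy", {"g1", "g2"}, set(), regions)
        assert report.stma_per_1000 == 0 and report.pct_regions_with_stma == 0

    def test_empty_gene_set_rates_missing(self):
        report = stma_metrics("empty", set(), {"g1"}, [])
        assert report.stma_per_1000 is None and report.stma_per_mb is None

    def test_build_table_hand_computed(self):
        regions = _toy_dataset()
        stma = {"g1", "g3"}
        control = stma_metrics("ctrl", {"g1", "g2", "g3", "g4"}, stma, regions)
        case = stma_metrics("case", {"g2", "g3"}, stma, regions[:3])
        case = fold_vs_control(case, control)
        table = build_table1([case, control])
        assert list(table.columns) == ["case", "ctrl"]
        assert table.loc["total_genes", "case"] == 2
        assert table.loc["stma_genes", "case"] == 1
        assert table.loc["stma_per_1000", "case"] == 500.0
        assert table.loc["fold_per_1000_vs_control", "case"] == 1.0
        assert table.loc["cnv_total_mb", "ctrl"] == 5.0
        assert table.loc["n_regions", "ctrl"] == 5

    def test_rounding_is_half_up(self):
        from stmaburden.stats import _round_half_up

        assert _round_half_up(0.165, 2) == 0.17
        assert _round_half_up(3.2361, 1) == 3.2
        assert _round_half_up(16.25, 1) == 16.3
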