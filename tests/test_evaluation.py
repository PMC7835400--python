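"""Levene bootstrap, mean-difference and homogeneity tests, aggregate
core-collection percentages."""

import numpy as np
import pytest

from germcore import (
    cc_properties,
    chi2_homogeneity,
    evaluate_collections,
    levene_bootstrap,
    mean_difference_test,
)
from germcore.evaluation_stats import QuantSummary, _levene_W

from conftest import make_clustered_table
from printed_tables import (
    COVERAGE_K_QUAL,
    COVERAGE_K_QUANT,
    COVERAGE_PCT_PRINTED,
    EC_VS_CC_PLANT_HEIGHT,
    OBSERVED_VS_IMPUTED_PLANT_HEIGHT,
    OBSERVED_VS_IMPUTED_PLANT_TYPE,
    QUALITATIVE,
)


class TestLeveneBootstrap:
    def test_identical_samples_give_one(self):
        x = np.arange(10.0)
        assert levene_bootstrap(x, x, B=200, seed=0) == 1.0

    def test_zero_variance_both_groups(self):
        assert levene_bootstrap([1.0, 1.0], [2.0, 2.0], B=50, seed=0) == 1.0

    def test_detects_threefold_sd_difference(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for rep in range(10):
            x_e = rng.normal(0, 1, 200)
            x_c = rng.normal(0, 3, 30)
            p = levene_bootstrap(x_e, x_c, B=1000, seed=rep)
            rejections += p < 0.05
        assert rejections >= 9

    def test_type_i_error_near_nominal(self):
        # equal-variance pairs; rejection rate should sit near alpha
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for rep in range(reps):
            x_e = rng.normal(0, 1, 40)
            x_c = rng.normal(0, 1, 15)
            p = levene_bootstrap(x_e, x_c, B=199, seed=rep)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_statistic_matches_scipy_levene(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 20)
        W = _levene_W([a, b])
        assert W == pytest.approx(
            stats.levene(a, b, center="mean").statistic
        )


class TestMeanDifference:
    def test_published_observed_vs_completed_summary(self):
        se, sc, p_printed = OBSERVED_VS_IMPUTED_PLANT_HEIGHT
        res = mean_difference_test(summary_e=se, summary_c=sc, levene_p=1.0)
        assert res.test == "student_t"
        assert round(res.p, 2) == p_printed

    def test_published_core_vs_entire_welch(self):
        se, sc, levene_p, p_printed = EC_VS_CC_PLANT_HEIGHT
        res = mean_difference_test(summary_e=se, summary_c=sc, levene_p=levene_p)
        assert res.test == "welch_t"
        assert round(res.p, 2) == p_printed
        assert res.significant

    def test_identical_summaries_p_one(self):
        res = mean_difference_test(
            summary_e=(50, 5.0, 1.0), summary_c=(50, 5.0, 1.0)
        )
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        same = mean_difference_test(
            summary_e=(10, 3.0, 0.0), summary_c=(10, 3.0, 0.0)
        )
        diff = mean_difference_test(
            summary_e=(10, 3.0, 0.0), summary_c=(10, 4.0, 0.0)
        )
        assert same.p == 1.0 and diff.p == 0.0

    def test_raw_samples_equal_summary_path(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 25)
        from_raw = mean_difference_test(a, b, levene_p=1.0)
        from_sum = mean_difference_test(
            summary_e=(40, a.mean(), a.std(ddof=1)),
            summary_c=(25, b.mean(), b.std(ddof=1)),
            levene_p=1.0,
        )
        assert from_raw.p == pytest.approx(from_sum.p)


class TestChi2Homogeneity:
    @pytest.mark.parametrize("trait", sorted(QUALITATIVE))
    def test_all_published_p_values(self, trait):
        ec, cc, p_printed, _, _ = QUALITATIVE[trait]
        res = chi2_homogeneity(ec, cc)
        assert round(res.p, 2) == pytest.approx(p_printed)

    def test_yates_only_for_two_categories(self):
        assert chi2_homogeneity([131, 68], [18, 12]).test == "chi2_yates"
        assert chi2_homogeneity([58, 79, 62], [9, 10, 11]).test == "chi2"

    def test_published_observed_vs_completed_2x2(self):
        a, b, p_printed = OBSERVED_VS_IMPUTED_PLANT_TYPE
        res = chi2_homogeneity(a, b)
        assert round(res.p, 2) == p_printed and res.significant

    def test_proportional_tables_give_p_one(self):
        res = chi2_homogeneity([10, 20, 30], [20, 40, 60])
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_single_shared_category(self):
        assert chi2_homogeneity([5, 0], [3, 0]).p == 1.0


class TestCCProperties:
    def test_identity_core_is_perfectly_representative(self):
        table, _ = make_clustered_table(seed=20, n=50)
        report = evaluate_collections(table, table, B=200, seed=0)
        assert report.MD_pct == pytest.approx(0.0)
        assert report.VD_pct == pytest.approx(0.0)
        assert report.CR_pct == pytest.approx(100.0)
        assert report.VR_pct == pytest.approx(100.0)
        assert report.coverage_combined_pct == pytest.approx(100.0)
        assert report.verdict

    def test_two_trait_hand_example(self):
        summaries = {
            "t1": (
                QuantSummary(10, 10.0, 4.0, 5.0, 0.2),
                QuantSummary(5, 8.0, 4.0, 5.0, 0.2),
            ),
            "t2": (
                QuantSummary(10, 6.0, 1.0, 2.0, 0.1),
                QuantSummary(5, 6.0, 1.0, 2.0, 0.1),
            ),
        }
        report = cc_properties(summaries, {"t1": (3, 3), "t2": (2, 2)})
        assert report.MD_pct == pytest.approx(12.5)  # (1/2)(2/8 + 0) x 100

    def test_published_coverage_from_cluster_counts(self):
        counts = {**COVERAGE_K_QUANT, **COVERAGE_K_QUAL}
        report = cc_properties({}, counts, qual_traits=set(COVERAGE_K_QUAL))
        assert round(report.coverage_quant_pct, 2) == COVERAGE_PCT_PRINTED["quantitative"]
        assert round(report.coverage_qual_pct, 2) == COVERAGE_PCT_PRINTED["qualitative"]
        assert round(report.coverage_combined_pct, 2) == COVERAGE_PCT_PRINTED["combined"]

    def test_subset_core_bounds(self):
        table, _ = make_clustered_table(seed=21, n=60)
        cc = table.subset_accessions(table.accession_ids[::3])
        report = evaluate_collections(table, cc, B=100, seed=0)
        assert report.CR_pct <= 100.0 + 1e-9
        assert report.coverage_combined_pct <= 100.0 + 1e-9

    def test_percentages_invariant_to_trait_order(self):
        summaries = {
            "a": (QuantSummary(9, 5.0, 2.0, 4.0, 0.3),
                  QuantSummary(4, 4.0, 3.0, 3.0, 0.4)),
            "b": (QuantSummary(9, 8.0, 1.0, 2.0, 0.1),
                  QuantSummary(4, 9.0, 2.0, 2.0, 0.2)),
        }
        counts = {"a": (4, 3), "b": (2, 2)}
        fwd = cc_properties(summaries, counts)
        rev = cc_properties(
            dict(reversed(list(summaries.items()))),
            dict(reversed(list(counts.items()))),
        )
        for attr in ("MD_pct", "VD_pct", "CR_pct", "VR_pct"):
            assert getattr(fwd, attr) == pytest.approx(getattr(rev, attr))

    def test_verdict_thresholds(self):
        from germcore.evaluation_stats import EvaluationReport, TraitTestResult

        base = dict(
            MD_pct=5.0, VD_pct=10.0, VR_pct=100.0,
            coverage_quant_pct=90.0, coverage_qual_pct=90.0,
            coverage_combined_pct=90.0,
        )
        good = EvaluationReport(CR_pct=85.0, pct_significant=10.0, **base)
        low_cr = EvaluationReport(CR_pct=75.0, pct_significant=10.0, **base)
        many_sig = EvaluationReport(CR_pct=85.0, pct_significant=30.0, **base)
        assert good.verdict and not low_cr.verdict and not many_sig.verdict
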