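import numpy as np
import pytest
from hypothesis import given, strategies as st

from donorgfr import (agreement, bland_altman_data, estimate_compensation_factor,
                      nested_model_test, predict_post, threshold_concordance,
                      univariable_regression)
from donorgfr.metrics import AnalysisConfig, MetricsError


class TestPredictPost:
    def test_worked_values(self):
        assert predict_post(100.0, 0.66) == pytest.approx(66.0)
        assert predict_post(94.0, 0.66) == pytest.approx(62.04)
        assert predict_post(87.3, 1.0) == pytest.approx(87.3)

    def test_non_positive_fatal(self):
        with pytest.raises(MetricsError):
            predict_post(-5.0)


class TestCompensationFactor:
    def test_exact_cases(self):
        pre = np.array([100.0, 80.0])
        assert estimate_compensation_factor(pre, pre)[0] == pytest.approx(1.0)
        f, pct = estimate_compensation_factor(pre, 0.66 * pre)
        assert f == pytest.approx(0.66) and pct == pytest.approx(-34.0)

    def test_mean_of_ratios(self):
        f, _ = estimate_compensation_factor([100.0, 80.0], [60.0, 56.0])
        assert f == pytest.approx(1 + np.mean([-0.40, -0.30]))  # 0.65

    def test_non_positive_pre_fatal(self):
        with pytest.raises(MetricsError):
            estimate_compensation_factor([100.0, 0.0], [60.0, 50.0])


class TestAgreement:
    def test_perfect_agreement(self):
        rep = agreement([90.0, 95.0, 100.0], [90.0, 95.0, 100.0])
        assert rep.mean_bias == 0 and rep.rmse == 0
        assert rep.p30 == 100.0 and rep.p10 == 100.0 and rep.r2 == pytest.approx(1.0)

    def test_three_pair_worked_fixture(self):
        """Hand arithmetic: biases (-10, 0, 10) against observed 90."""
        rep = agreement([80.0, 90.0, 100.0], [90.0, 90.0, 90.0])
        assert rep.mean_bias == pytest.approx(0.0)
        assert rep.rmse == pytest.approx(np.sqrt(200 / 3), abs=1e-9)  # 8.1650
        assert rep.p30 == pytest.approx(100.0)
        assert rep.p10 == pytest.approx(100.0 / 3)
        assert rep.iqr_bias == pytest.approx((-5.0, 5.0))

    def test_translation_shifts_bias_only(self, rng):
        pred = rng.uniform(60, 120, 40)
        obs = rng.uniform(60, 120, 40)
        a, b = agreement(pred, obs), agreement(pred + 7.0, obs)
        assert b.mean_bias == pytest.approx(a.mean_bias + 7.0)
        assert b.r2 == pytest.approx(a.r2, rel=1e-9)

    def test_rmse_decomposition_identity(self, rng):
        """rmse² = mean_bias² + population variance of the bias."""
        for _ in range(100):
            n = rng.integers(5, 50)
            pred, obs = rng.uniform(40, 140, n), rng.uniform(40, 140, n)
            rep = agreement(pred, obs)
            var = np.var(pred - obs)  # 1/n
            assert rep.rmse ** 2 == pytest.approx(rep.mean_bias ** 2 + var, rel=1e-9)

    def test_scaling_scales_bias_not_percentages(self, rng):
        pred = rng.uniform(60, 120, 30)
        obs = rng.uniform(60, 120, 30)
        a, b = agreement(pred, obs), agreement(3 * pred, 3 * obs)
        assert b.mean_bias == pytest.approx(3 * a.mean_bias)
        assert b.rmse == pytest.approx(3 * a.rmse)
        assert b.p30 == a.p30 and b.p10 == a.p10

    def test_p10_never_exceeds_p30(self, rng):
        for _ in range(20):
            pred, obs = rng.uniform(40, 140, 25), rng.uniform(40, 140, 25)
            rep = agreement(pred, obs)
            assert 0 <= rep.p10 <= rep.p30 <= 100

    def test_boundary_error_counts_as_failure(self):
        # |bias|/observed exactly 0.10 -> outside P10 (strict inequality)
        rep = agreement([110.0, 100.0], [100.0, 100.0])
        assert rep.p10 == pytest.approx(50.0)

    def test_small_or_invalid_inputs_fatal(self):
        with pytest.raises(MetricsError):
            agreement([100.0], [90.0])
        with pytest.raises(MetricsError):
            agreement([100.0, 90.0], [90.0, -1.0])


class TestUnivariableRegression:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        s = univariable_regression(x, 2 * x + 1)
        assert s.sbeta == pytest.approx(1.0) and s.r2 == pytest.approx(1.0)
        assert univariable_regression(x, -x).sbeta == pytest.approx(-1.0)

    def test_sbeta_equals_pearson_r(self, rng):
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        s = univariable_regression(x, y)
        # independent closed-form Pearson r
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert s.sbeta == pytest.approx(r, abs=1e-12)
        assert s.r2 == pytest.approx(r ** 2, abs=1e-12)

    def test_constant_x_fatal(self):
        with pytest.raises(MetricsError):
            univariable_regression(np.ones(5), np.arange(5.0))


class TestNestedModel:
    def test_duplicated_column_rank_deficient(self, rng):
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, -1.0] + rng.normal(size=30)
        with pytest.raises(MetricsError, match="rank"):
            nested_model_test(y, x, x[:, 0])

    def test_pure_noise_adds_nothing(self, rng):
        x = rng.normal(size=(2000, 2))
        y = x @ [1.0, -1.0] + rng.normal(size=2000)
        noise = rng.normal(size=2000)
        r2b, r2f, p = nested_model_test(y, x, noise)
        assert r2f == pytest.approx(r2b, abs=0.005)
        assert p > 0.05

    def test_informative_column_highly_significant(self, rng):
        x = rng.normal(size=(200, 2))
        y = x @ [0.5, 0.5] + rng.normal(size=200)
        added = y + 0.01 * rng.normal(size=200)
        r2b, r2f, p = nested_model_test(y, x, added)
        assert r2f > r2b
        assert p < 1e-6
        # cross-check the partial F statistic from residual sums of squares
        import statsmodels.api as sm
        rss = lambda X: sm.OLS(y, sm.add_constant(X)).fit().ssr
        rss_b, rss_f = rss(x), rss(np.column_stack([x, added]))
        F = (rss_b - rss_f) / (rss_f / (200 - 4))
        from scipy import stats
        assert stats.f.sf(F, 1, 200 - 4) == pytest.approx(p, rel=1e-6)


class TestThresholdConcordance:
    def test_single_discordant_pair(self):
        tab = threshold_concordance([95.0], [85.0], thresholds=(90.0,))
        assert tab.loc[0, "egfr_ge_mgfr_lt"] == 1
        assert tab.loc[0, ["both_ge", "egfr_lt_mgfr_ge", "both_lt"]].sum() == 0

    def test_equal_vectors_fully_concordant(self, rng):
        v = rng.uniform(40, 130, 50)
        tab = threshold_concordance(v, v)
        assert (tab["egfr_ge_mgfr_lt"] == 0).all() and (tab["egfr_lt_mgfr_ge"] == 0).all()

    def test_six_pair_enumeration_with_ties_as_ge(self):
        egfr = [60.0, 59.9, 70.0, 50.0, 65.0, 55.0]
        mgfr = [60.0, 60.0, 55.0, 45.0, 80.0, 61.0]
        tab = threshold_concordance(egfr, mgfr, thresholds=(60.0,))
        row = tab.iloc[0]
        assert (row["both_ge"], row["egfr_ge_mgfr_lt"],
                row["egfr_lt_mgfr_ge"], row["both_lt"]) == (2, 1, 2, 1)


class TestBlandAltman:
    def test_equal_pairs_zero_limits(self):
        tab, summ = bland_altman_data([90.0, 100.0], [90.0, 100.0])
        assert (tab["difference"] == 0).all()
        assert summ["loa_low"] == 0 == summ["loa_high"]

    def test_single_pair(self):
        tab, _ = bland_altman_data([100.0], [90.0])
        assert tab.iloc[0].tolist() == pytest.approx([95.0, 10.0])

    def test_limits_match_direct_formula(self):
        e = np.array([80.0, 92.0, 101.0, 75.0, 99.0])
        m = np.array([85.0, 90.0, 95.0, 80.0, 105.0])
        _, summ = bland_altman_data(e, m)
        d = e - m
        assert summ["mean_difference"] == pytest.approx(d.mean())
        assert summ["loa_low"] == pytest.approx(d.mean() - 1.96 * d.std())
        assert summ["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std())


class TestAnalysisConfig:
    def test_invalid_values_fatal(self):
        with pytest.raises(MetricsError):
            AnalysisConfig(compensation_factor=1.5)
        with pytest.raises(MetricsError):
            AnalysisConfig(thresholds=(90.0, -60.0))
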