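"""Decay-model evaluation, quasi-likelihood fitting, QAIC, class comparison."""

import numpy as np
import pytest

from fissionet.larmodels import (
    MODELS,
    by_critical_values,
    compare_classes,
    evaluate_model,
    fit_model,
    fit_model_set,
    pearson_chat,
    pooled_t,
    qaic,
    select_model,
)
from fissionet.synthdata import simulate_lar_counts, study_design_lag_weights


class TestEvaluate:
    def test_two_ca_at_zero_is_amplitude_sum(self):
        assert evaluate_model("TWO_CA_RD", [0.3, 1.0, 0.5, 0.01], 0.0) == pytest.approx(0.8)

    def test_zero_rates_constant(self):
        taus = np.array([0.0, 5.0, 50.0])
        g = evaluate_model("TWO_CA_RD", [0.3, 0.0, 0.5, 0.0], taus)
        assert np.allclose(g, 0.8)

    def test_high_risk_point_estimates(self):
        # the fitted high-risk curve starts at a + c = 0.01 + 0.69 = 0.70
        g0 = evaluate_model("TWO_CA_RD", [0.01, 1.03, 0.69, 0.01], 0.0)
        assert g0 == pytest.approx(0.70)

    def test_linear_form(self):
        assert evaluate_model("LINEAR", [0.5, -0.01], 10.0) == pytest.approx(0.4)

    def test_negative_rate_grows(self):
        g = evaluate_model("CA_RD", [0.2, -0.05], np.array([0.0, 10.0]))
        assert g[1] > g[0]


class TestFitting:
    def test_constant_g_recovery(self):
        lags = np.arange(1.0, 51.0)
        den = np.full(50, 5000)
        num = simulate_lar_counts("CC_RD", [0.7], lags, den, seed=1)
        fit = fit_model(lags, num, den, "CC_RD", seed=2)
        assert abs(fit.params["a"] - 0.7) < 0.01

    def test_two_timescale_recovery(self):
        lags, den = study_design_lag_weights(120_000)
        truth = [0.3, 1.0, 0.5, 0.01]
        num = simulate_lar_counts("TWO_CA_RD", truth, lags, den, seed=3)
        fit = fit_model(lags, num, den, "TWO_CA_RD", seed=4)
        assert abs(fit.params["a"] - 0.3) / 0.3 < 0.2
        assert abs(fit.params["b"] - 1.0) / 1.0 < 0.2

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError):
            fit_model(np.array([1.0]), np.array([5.0]), np.array([10.0]), "TWO_CA_RD")

    def test_nested_loglik_ordering(self):
        lags, den = study_design_lag_weights(20_000)
        num = simulate_lar_counts("CC_CA_RD", [0.3, 0.4, 0.5], lags, den, seed=5)
        small = fit_model(lags, num, den, "CA_RD", seed=6)
        big = fit_model(lags, num, den, "TWO_CA_RD", seed=6)
        assert big.lnql >= small.lnql - 1e-6

    def test_amplitude_shrinkage_on_single_exponential_data(self):
        # TWO_CA_RD fitted to CA_RD truth: the redundant component either
        # contributes (almost) nothing over the observable lags or merges
        # with the real one (lags start at 1, so a large-b term with any
        # nominal amplitude is invisible: its effective size is a e^{-b})
        hits = 0
        for seed in range(20):
            lags, den = study_design_lag_weights(50_000)
            num = simulate_lar_counts("CA_RD", [0.6, 0.3], lags, den, seed=seed)
            fit = fit_model(lags, num, den, "TWO_CA_RD", seed=seed + 1000)
            a, b, c, d = (fit.params[p] for p in ("a", "b", "c", "d"))
            eff = min(a * np.exp(-b * lags[0]), c * np.exp(-d * lags[0]))
            if eff < 0.05 or abs(b - d) < 0.1:
                hits += 1
        assert hits >= 16

    def test_ca_rd_data_prefers_ca_rd_over_two_ca(self):
        wins = 0
        for seed in range(20):
            lags, den = study_design_lag_weights(50_000)
            num = simulate_lar_counts("CA_RD", [0.6, 0.3], lags, den, seed=seed)
            fits = fit_model_set(lags, num, den, models=("CA_RD", "TWO_CA_RD"), seed=seed)
            best, _ = select_model(fits)
            wins += best.model.name == "CA_RD"
        assert wins >= 16

    def test_amplitude_sum_bounded(self):
        lags, den = study_design_lag_weights(20_000)
        num = simulate_lar_counts("TWO_CA_RD", [0.45, 2.0, 0.5, 0.005], lags, den, seed=9)
        fit = fit_model(lags, num, den, "TWO_CA_RD", seed=10)
        assert fit.params["a"] + fit.params["c"] <= 1.0 + 1e-6


class TestQAIC:
    def test_equals_aic_when_no_overdispersion(self):
        lags = np.arange(1.0, 30.0)
        den = np.full(29, 1000)
        num = simulate_lar_counts("CC_RD", [0.4], lags, den, seed=11)
        fit = fit_model(lags, num, den, "CC_RD", seed=12)
        assert qaic(fit, 1.0) == pytest.approx(-2 * fit.lnql + 2)

    def test_chat_near_one_for_binomial_data(self):
        # true binomial sampling: average overdispersion estimate ~ 1
        lags, den = study_design_lag_weights(50_000)
        chats = []
        for seed in range(10):
            num = simulate_lar_counts("TWO_CA_RD", [0.3, 1.0, 0.5, 0.01], lags, den, seed=seed)
            fit = fit_model(lags, num, den, "TWO_CA_RD", seed=seed + 500)
            chats.append(pearson_chat(fit, lags, num, den))
        assert np.mean(chats) < 1.3

    def test_single_fit_selected_unchanged(self):
        lags = np.arange(1.0, 30.0)
        den = np.full(29, 500)
        num = simulate_lar_counts("CC_RD", [0.4], lags, den, seed=15)
        fits = fit_model_set(lags, num, den, models=("CC_RD",), seed=16)
        best, table = select_model(fits)
        assert best is fits[0]
        assert len(table) == 1


class TestClassComparison:
    def test_by_largest_rank_critical_value(self):
        # m = 4 dependent comparisons at alpha = 0.05
        crits = by_critical_values(4, 0.05)
        assert crits[-1] == pytest.approx(0.05 / (1 + 1 / 2 + 1 / 3 + 1 / 4))
        assert round(crits[-1], 3) == 0.024

    def test_pooled_df_seven_vs_five(self):
        x1, x2 = np.arange(7.0), np.arange(5.0) + 0.5
        _, df, _ = pooled_t(x1, x2)
        assert df == 10

    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = pooled_t(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, 7), rng.normal(0.8, 1, 5)
        t, df, p = pooled_t(x1, x2)
        ref = stats.ttest_ind(x1, x2, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_compare_classes_flags(self):
        rng = np.random.default_rng(1)
        grouped = {
            "high": {
                "a": rng.normal(0.0, 0.01, 7),
                "b": rng.normal(1.0, 0.05, 7),
                "c": rng.normal(0.7, 0.05, 7),
                "d": rng.normal(0.01, 0.005, 7),
            },
            "low": {
                "a": rng.normal(0.3, 0.01, 5),
                "b": rng.normal(0.2, 0.05, 5),
                "c": rng.normal(0.2, 0.05, 5),
                "d": rng.normal(0.012, 0.005, 5),
            },
        }
        comps = compare_classes(grouped)
        by_name = {c.parameter: c for c in comps}
        assert all(c.df == 10 for c in comps)
        assert by_name["a"].significant and by_name["b"].significant
        assert not by_name["d"].significant

    def test_zero_variance_unequal_means_flagged(self):
        grouped = {"high": {"a": np.ones(3)}, "low": {"a": np.zeros(3)}}
        with pytest.raises(ValueError, match="zero within-class variance"):
            compare_classes(grouped)
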