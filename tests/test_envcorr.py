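"""Generalized differencing, pairwise correlations and AR(1)-GLS models."""

import numpy as np
import pandas as pd
import pytest

from cladewane.simulate import ar1_series
from cladewane.envcorr import (
    aicc,
    akaike_weights,
    generalized_difference,
    gls_ar1,
    model_compare,
    pairwise_correlation,
    run_windows,
)


class TestGeneralizedDifference:
    def test_pure_trend_vanishes(self):
        t = np.arange(20.0)
        out = generalized_difference(3.0 - 0.5 * t, t)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_white_noise_nearly_unchanged(self):
        rng = np.random.default_rng(0)
        t = np.arange(500.0)
        y = rng.standard_normal(500)
        out = generalized_difference(y, t)
        resid = y - np.polyval(np.polyfit(t, y, 1), t)
        assert np.mean(np.abs(out - resid[1:])) < 0.1

    def test_removes_ar1_autocorrelation(self):
        rng = np.random.default_rng(1)
        t = np.arange(400.0)
        hits = []
        for _ in range(20):
            y = ar1_series(400, 0.8, 1.0, rng)
            d = generalized_difference(y, t)
            dc = d - d.mean()
            lag1 = np.sum(dc[1:] * dc[:-1]) / np.sum(dc**2)
            hits.append(abs(lag1) < 2 / np.sqrt(len(d)))
        assert np.mean(hits) > 0.8

    def test_constant_series_returns_zeros(self):
        out = generalized_difference(np.full(10, 2.0), np.arange(10.0))
        np.testing.assert_allclose(out, 0.0)


class TestPairwise:
    def test_identical_series_perfectly_correlated(self):
        rng = np.random.default_rng(2)
        t = np.arange(30.0)
        x = rng.standard_normal(30).cumsum()
        r, p = pairwise_correlation(x, x, t)
        assert r == pytest.approx(1.0)

    def test_sign_of_anticorrelation(self):
        rng = np.random.default_rng(3)
        t = np.arange(40.0)
        x = rng.standard_normal(40)
        r, _ = pairwise_correlation(x, -x + 0.01 * rng.standard_normal(40), t)
        assert r < -0.9

    def test_spearman_option(self):
        rng = np.random.default_rng(4)
        t = np.arange(30.0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r, p = pairwise_correlation(x, y, t, method="spearman")
        assert -1 <= r <= 1 and 0 <= p <= 1


class TestGlsAr1:
    def test_matches_ols_when_independent(self):
        """With phi ~ 0, the GLS betas match ordinary least squares."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = 2.0 + 0.5 * x + rng.standard_normal(300)
        fit = gls_ar1(y, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(fit.phi) < 0.15
        assert fit.beta0 == pytest.approx(ols.params[0], abs=0.02)
        assert fit.beta1 == pytest.approx(ols.params[1], abs=0.02)

    def test_loglik_at_zero_phi_equals_ols_loglik(self):
        import statsmodels.api as sm

        from cladewane.envcorr import _ar1_profile_loglik

        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        y = 1.0 + 0.3 * x + rng.standard_normal(50)
        X = np.column_stack([np.ones(50), x])
        ll, *_ = _ar1_profile_loglik(0.0, y, X)
        ols = sm.OLS(y, X).fit()
        assert ll == pytest.approx(ols.llf, abs=1e-8)

    def test_recovers_serial_correlation(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(400)
        y = 1.0 + 0.8 * x + ar1_series(400, 0.6, 1.0, rng)
        fit = gls_ar1(y, x)
        assert fit.phi == pytest.approx(0.6, abs=0.12)
        assert fit.beta1 == pytest.approx(0.8, abs=0.1)

    def test_matches_statsmodels_sarimax(self):
        """Independent ML cross-check: regression with AR(1) errors."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.standard_normal(150)
        y = 0.5 + 1.2 * x + ar1_series(150, 0.5, 1.0, rng)
        ours = gls_ar1(y, x)
        theirs = sm.tsa.SARIMAX(y, exog=np.column_stack([np.ones(150), x]),
                                order=(1, 0, 0), trend="n").fit(disp=0)
        assert ours.beta1 == pytest.approx(theirs.params[1], abs=0.02)
        assert ours.phi == pytest.approx(theirs.params[2], abs=0.03)
        assert ours.loglik == pytest.approx(theirs.llf, abs=0.5)

    def test_intercept_only_model(self):
        rng = np.random.default_rng(9)
        y = 5.0 + ar1_series(100, 0.4, 1.0, rng)
        fit = gls_ar1(y, include_predictor=False)
        assert fit.beta1 is None
        assert fit.k == 3
        assert fit.beta0 == pytest.approx(5.0, abs=0.5)


class TestModelSelection:
    def test_aicc_formula(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_weights_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        np.testing.assert_allclose(w, [0.731, 0.269], atol=5e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_weights_shift_invariant(self):
        a = np.array([10.0, 11.5, 14.0])
        np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 1000))

    def test_true_predictor_wins(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(60)
        noise = rng.standard_normal(60)
        y = 2.0 + 1.5 * x + 0.3 * ar1_series(60, 0.3, 1.0, rng)
        table = model_compare(y, {"signal": x, "noise": noise})
        assert table.iloc[0]["model"] == "signal"
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table.iloc[0]["weight"] > 0.9


class TestWindows:
    def _dataset(self, seed=11, n=16):
        rng = np.random.default_rng(seed)
        bins = [f"b{i}" for i in range(n)]
        x = ar1_series(n, 0.3, 1.0, rng)
        y = 0.5 * x + 0.5 * ar1_series(n, 0.3, 1.0, rng)
        response = pd.Series(y, index=bins)
        predictors = pd.DataFrame({"x": x}, index=bins)
        times = pd.Series(np.arange(n, dtype=float), index=bins)
        return response, predictors, times, bins

    def test_identical_windows_identical_results(self):
        response, predictors, times, bins = self._dataset()
        res = run_windows(response, predictors, times,
                          {"w1": bins, "w2": list(bins)})
        assert res["w1"]["pairwise"] == res["w2"]["pairwise"]
        pd.testing.assert_frame_equal(res["w1"]["models"], res["w2"]["models"])

    def test_small_window_skipped(self):
        response, predictors, times, bins = self._dataset()
        res = run_windows(response, predictors, times, {"tiny": bins[:3]})
        assert res["tiny"]["skipped"]

    def test_terminal_pulse_drives_full_window_weight(self):
        """A predictor that only matters through a terminal-bin extinction
        pulse earns more Akaike weight on the full window than on the
        truncated one, on average over seeds."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 14
            bins = [f"b{i}" for i in range(n)]
            x = ar1_series(n, 0.3, 1.0, rng)
            y = ar1_series(n, 0.3, 0.5, rng)
            x[-1] += 8.0            # environmental spike in the terminal bin
            y[-1] = -1.0 * x[-1]    # extinction pulse tracks the spike
            response = pd.Series(y, index=bins)
            predictors = pd.DataFrame({"x": x}, index=bins)
            times = pd.Series(np.arange(n, dtype=float), index=bins)
            res = run_windows(response, predictors, times,
                              {"full": bins, "truncated": bins[:-1]})
            w_full = res["full"]["models"].set_index("model").loc["x", "weight"]
            w_trunc = res["truncated"]["models"].set_index("model").loc["x", "weight"]
            wins += w_full > w_trunc
        assert wins >= n_seeds * 0.6
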