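"""Unit and property tests for the logistic fitter and nested tests."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from cumulrisk.glm_core import (
    DegenerateOutcomeError,
    DesignMatrix,
    RankDeficientError,
    fit_logistic,
    lr_test_partial,
    lr_test_sequential,
    nagelkerke_r2,
    wald_ci,
)

rng = np.random.default_rng(42)


def _nll(beta, X, y):
    eta = X @ beta
    return np.sum(np.log1p(np.exp(eta)) - y * eta)


def _brute_force_mle(X, y):
    """Independent oracle: direct numerical minimisation of the exact
    negative log-likelihood with analytic gradient."""
    res = minimize(
        _nll,
        np.zeros(X.shape[1]),
        args=(X, y),
        jac=lambda b, X, y: X.T @ (1 / (1 + np.exp(-(X @ b))) - y),
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.coefficients[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # exposed: 40 cases / 10 controls; unexposed: 10 cases / 40 controls
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        X = np.column_stack([np.ones(100), x])
        fit = fit_logistic(X, y)
        assert fit.coefficients[1] == pytest.approx(np.log(16.0), abs=1e-8)
        assert fit.converged

    def test_constant_outcome_raises(self):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(X, np.zeros(20))

    def test_rank_deficiency_names_columns(self):
        x = rng.normal(size=30)
        X = DesignMatrix(
            np.column_stack([np.ones(30), x, 2 * x]), ["intercept", "a", "a_copy"]
        )
        y = (rng.random(30) < 0.5).astype(float)
        y[0], y[1] = 0, 1
        with pytest.raises(RankDeficientError) as exc:
            fit_logistic(X, y)
        assert set(exc.value.columns) <= {"a", "a_copy"}
        assert exc.value.columns  # at least one collinear member is named

    def test_perfect_separation_flagged_and_capped(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert fit.separation and not fit.converged
        assert np.all(np.abs(fit.coefficients) <= 15.0 + 1e-9)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_brute_force_optimizer(self, p):
        """IRLS coefficients agree with a direct likelihood maximiser."""
        for seed in range(4):
            r = np.random.default_rng(100 + seed)
            n = 250
            X = np.column_stack([np.ones(n), r.normal(size=(n, p))])
            eta = X @ np.r_[0.2, r.normal(scale=0.7, size=p)]
            y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            oracle = _brute_force_mle(X, y)
            assert np.max(np.abs(fit.coefficients - oracle)) < 1e-6

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        r = np.random.default_rng(3)
        X = np.column_stack([np.ones(300), r.normal(size=(300, 2))])
        y = (r.random(300) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.deviance, ref.deviance, rtol=1e-10)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.covariance)), ref.bse, rtol=1e-5
        )

    def test_deviance_identity_and_psd_covariance(self):
        r = np.random.default_rng(9)
        X = np.column_stack([np.ones(150), r.normal(size=(150, 2))])
        y = (r.random(150) < 0.5).astype(float)
        fit = fit_logistic(X, y)
        assert fit.deviance == pytest.approx(-2 * fit.log_likelihood)
        assert fit.deviance >= 0
        eig = np.linalg.eigvalsh((fit.covariance + fit.covariance.T) / 2)
        assert eig.min() > -1e-10

    def test_deviance_never_increases_with_added_predictor(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 80
            X = np.column_stack([np.ones(n), r.normal(size=(n, 3))])
            y = (r.random(n) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            d_small = fit_logistic(X[:, :3], y).deviance
            d_big = fit_logistic(X, y).deviance
            assert d_big <= d_small + 1e-8


class TestNestedTests:
    def _design(self, cols, names):
        return DesignMatrix(np.column_stack(cols), names)

    def test_sequential_statistics_telescope_exactly(self):
        r = np.random.default_rng(21)
        n = 300
        X = np.column_stack([np.ones(n), r.normal(size=(n, 4))])
        y = (r.random(n) < 0.5).astype(float)
        dm = DesignMatrix(X, ["intercept", "a", "b", "c", "d"])
        res = lr_test_sequential(dm, y, [2, 3, 5])
        total = sum(t.statistic for t in res)
        d_null = fit_logistic(X[:, :2], y).deviance
        d_full = fit_logistic(X, y).deviance
        assert total == pytest.approx(d_null - d_full, abs=1e-8)
        assert [t.df for t in res] == [1, 2]

    def test_redundant_marker_has_no_sequential_effect(self):
        r = np.random.default_rng(2)
        n = 200
        cov = r.normal(size=n)
        y = (r.random(n) < 1 / (1 + np.exp(-cov))).astype(float)
        dup = cov + r.normal(scale=1e-6, size=n)
        dm = self._design([np.ones(n), cov, dup], ["intercept", "cov", "dup"])
        res = lr_test_sequential(dm, y, [2, 3])
        assert res[0].statistic < 1e-4
        assert res[0].p_value > 0.99

    def test_strong_marker_entered_first_is_detected(self):
        r = np.random.default_rng(7)
        n = 2000
        x = r.binomial(2, 0.3, size=n).astype(float)
        y = (r.random(n) < 1 / (1 + np.exp(-(-1 + np.log(2) * x)))).astype(float)
        dm = self._design([np.ones(n), x], ["intercept", "x"])
        res = lr_test_sequential(dm, y, [1, 2])
        # oracle: direct two-fit deviance difference
        d0 = fit_logistic(np.ones((n, 1)), y).deviance
        d1 = fit_logistic(dm.values, y).deviance
        assert res[0].statistic == pytest.approx(d0 - d1, abs=1e-8)
        assert res[0].p_value < 1e-5

    def test_partial_equals_brute_force_refit(self):
        r = np.random.default_rng(13)
        n = 20
        X = np.column_stack([np.ones(n), r.normal(size=(n, 2))])
        y = np.r_[np.ones(8), np.zeros(12)]
        dm = DesignMatrix(X, ["intercept", "a", "b"])
        res = lr_test_partial(dm, y, "b")
        d_red = fit_logistic(X[:, :2], y).deviance
        d_full = fit_logistic(X, y).deviance
        assert res.statistic == pytest.approx(d_red - d_full, abs=1e-10)
        assert res.df == 1

    def test_partial_equals_sequential_for_single_predictor(self):
        r = np.random.default_rng(17)
        n = 150
        x = r.normal(size=n)
        y = (r.random(n) < 0.5).astype(float)
        dm = self._design([np.ones(n), x], ["intercept", "x"])
        seq = lr_test_sequential(dm, y, [1, 2])[0]
        par = lr_test_partial(dm, y, "x")
        assert par.statistic == pytest.approx(seq.statistic, abs=1e-10)

    def test_near_duplicate_predictors_are_mutually_nonsignificant(self):
        """Two markers in near-perfect LD cannot both stay significant."""
        r = np.random.default_rng(23)
        n = 500
        x = r.binomial(2, 0.3, n).astype(float)
        x2 = x + r.normal(scale=1e-3, size=n)
        y = (r.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))).astype(float)
        dm = self._design([np.ones(n), x, x2], ["intercept", "m1", "m2"])
        assert lr_test_partial(dm, y, "m1").p_value > 0.05
        assert lr_test_partial(dm, y, "m2").p_value > 0.05

    @pytest.mark.parametrize("kind", ["sequential", "partial"])
    def test_null_p_values_are_uniform(self, kind):
        """Type-I calibration: permuted-phenotype p-values ~ Uniform(0,1)."""
        r = np.random.default_rng(31)
        n = 120
        pvals = []
        for _ in range(500):
            x = r.normal(size=n)
            y = (r.random(n) < 0.4).astype(float)
            dm = self._design([np.ones(n), x], ["intercept", "x"])
            if kind == "sequential":
                pvals.append(lr_test_sequential(dm, y, [1, 2])[0].p_value)
            else:
                pvals.append(lr_test_partial(dm, y, "x").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        null = fit_logistic(np.ones((100, 1)), y)
        assert nagelkerke_r2(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictor_scores_one(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = x.copy()
        X = np.column_stack([np.ones(100), x])
        fit = fit_logistic(X, y)
        null = fit_logistic(np.ones((100, 1)), y)
        assert nagelkerke_r2(fit, null) > 0.999

    def test_matches_hand_computed_deviances(self):
        # 2x2 worked data: exposed 40/10, unexposed 10/40
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        X = np.column_stack([np.ones(100), x])
        fit = fit_logistic(X, y)
        null = fit_logistic(np.ones((100, 1)), y)
        # saturated-group deviances computed from first principles
        d_full = -2 * (
            40 * np.log(0.8) + 10 * np.log(0.2) + 10 * np.log(0.2) + 40 * np.log(0.8)
        )
        d_null = -2 * 100 * np.log(0.5)
        expect = (1 - np.exp((d_full - d_null) / 100)) / (1 - np.exp(-d_null / 100))
        assert nagelkerke_r2(fit, null) == pytest.approx(expect, abs=1e-8)

    def test_degenerate_null_raises(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        fit = fit_logistic(np.ones((10, 1)), y)
        fake_null = fit_logistic(np.ones((10, 1)), y)
        fake_null.log_likelihood = 0.0
        with pytest.raises(ValueError):
            nagelkerke_r2(fit, fake_null)


class TestWaldCI:
    def _fit_with(self, beta, se):
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_logistic(np.ones((20, 1)), y)
        fit.coefficients = np.array([beta])
        fit.covariance = np.array([[se**2]])
        fit.predictor_names = ["x"]
        return fit

    def test_zero_beta_gives_unit_or_symmetric_ci(self):
        or_, lo, hi = wald_ci(self._fit_with(0.0, 0.3), "x")
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, abs=1e-12)

    def test_zero_se_collapses_interval(self):
        assert wald_ci(self._fit_with(np.log(2), 0.0), "x") == pytest.approx(
            (2.0, 2.0, 2.0)
        )

    def test_reported_precision_example(self):
        or_, lo, hi = wald_ci(self._fit_with(0.3365, 0.05), "x")
        assert round(or_, 2) == 1.40
        assert round(lo, 2) == 1.27
        assert round(hi, 2) == 1.54

    def test_nonconverged_fit_rejected(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(np.column_stack([np.ones(20), x]), x.copy())
        assert not fit.converged
        with pytest.raises(ValueError):
            wald_ci(fit, "x1")
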