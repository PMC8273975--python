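"""Estimator correctness: closed forms, numeric oracles, variance identities."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

import stratamiss as sm
from stratamiss.estimators import (
    SingleUnitStratumError,
    SingularDesignError,
    _design_frame,
)
from stratamiss.popgen import dummies


def two_by_two(a, b, c, d):
    """y/covariate data with cells: exposed (a successes, b failures),
    unexposed (c successes, d failures)."""
    g = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = pd.DataFrame({"intercept": np.ones_like(y), "g": g})
    return y, X


class TestFitLogistic:
    def test_saturated_two_by_two_closed_form(self):
        # cells (30,10,20,40): slope log((30/10)/(20/40)) = log 6, intercept log(1/2)
        y, X = two_by_two(30, 10, 20, 40)
        fit = sm.fit_logistic(y, X)
        assert fit.converged
        assert fit.coefficients["g"] == pytest.approx(np.log(6), abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(0.5), abs=1e-8)

    def test_balanced_independent_covariate_zero_coefficient(self):
        y, X = two_by_two(25, 25, 25, 25)
        fit = sm.fit_logistic(y, X)
        assert fit.coefficients["g"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_weights_match_unweighted(self, rng):
        n = 400
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < expit(0.3 - 0.7 * X.x)).astype(float)
        f0 = sm.fit_logistic(y, X)
        f1 = sm.fit_logistic(y, X, weights=np.full(n, 3.7))
        np.testing.assert_allclose(
            f0.coefficients.values, f1.coefficients.values, atol=1e-10
        )

    def test_rank_deficient_design_names_columns(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        X = pd.DataFrame({"intercept": 1.0, "a": [1, 0, 1, 0], "b": [2, 0, 2, 0]},
                         index=range(4), dtype=float)
        with pytest.raises(SingularDesignError, match="rank deficient"):
            sm.fit_logistic(y, X)

    def test_separation_plateaus_without_raising(self, rng):
        # a zero-success cell drives its coefficient to a large negative
        # plateau; the fit returns (deviance-converged, like R's glm) and
        # is retained rather than raised
        n = 300
        g = np.r_[np.ones(40), np.zeros(n - 40)]
        y = (rng.random(n) < 0.4).astype(float)
        y[:40] = 0.0  # complete separation in the exposed cell
        X = pd.DataFrame({"intercept": np.ones(n), "g": g})
        fit = sm.fit_logistic(y, X)
        assert fit.coefficients["g"] < -10
        assert fit.se["g"] > 10  # the Wald interval is essentially unbounded

    def test_exhausted_iterations_flagged_nonconverged(self, rng):
        n = 400
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < expit(1.5 * X.x)).astype(float)
        fit = sm.fit_logistic(y, X, max_iter=2)
        assert not fit.converged
        assert fit.n_iterations == 2

    def test_loglik_matches_statsmodels(self, rng):
        n = 500
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n),
                          "g": (rng.random(n) < 0.3).astype(float)})
        y = (rng.random(n) < expit(-0.2 + 0.5 * X.x - 0.4 * X.g)).astype(float)
        fit = sm.fit_logistic(y, X)
        ref = smapi.GLM(y, X, family=smapi.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients.values, ref.params.values, atol=1e-8)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_irls_matches_generic_optimizer(self, seed):
        # brute-force oracle: numerically maximize the weighted log-likelihood
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             (rng.random(n) < 0.5).astype(float)])
        beta_true = rng.uniform(-1, 1, 3)
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        w = rng.uniform(0.5, 4.0, n)
        if y.sum() in (0, n):
            return  # degenerate draw: no information about the slope

        def nll(beta):
            eta = X @ beta
            return -np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        def grad(beta):
            return -X.T @ (w * (y - expit(X @ beta)))

        res = minimize(nll, np.zeros(3), jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        fit = sm.fit_logistic(y, X, weights=w)
        if fit.converged and np.max(np.abs(res.x)) < 10:
            np.testing.assert_allclose(fit.coefficients.values, res.x, atol=1e-6)


class TestVariance:
    def test_intercept_only_binomial_closed_form(self):
        # k successes of n: Var(b0) = 1 / (n p (1-p))
        n, k = 80, 30
        y = np.r_[np.ones(k), np.zeros(n - k)]
        X = pd.DataFrame({"intercept": np.ones(n)})
        fit = sm.fit_logistic(y, X)
        p = k / n
        assert fit.vcov.iloc[0, 0] == pytest.approx(1 / (n * p * (1 - p)), rel=1e-6)

    def test_stacking_data_halves_variance(self, rng):
        n = 200
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < expit(0.2 + 0.5 * X.x)).astype(float)
        f1 = sm.fit_logistic(y, X)
        X2 = pd.concat([X, X], ignore_index=True)
        f2 = sm.fit_logistic(np.r_[y, y], X2)
        np.testing.assert_allclose(f2.vcov.values, f1.vcov.values / 2, rtol=1e-6)

    def test_matches_finite_difference_hessian(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < expit(-0.3 + 0.6 * X[:, 1])).astype(float)
        w = rng.uniform(1, 3, n)
        fit = sm.fit_logistic(y, X, weights=w)
        beta = fit.coefficients.values

        def ll(b):
            eta = X @ b
            return np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        eps = 1e-5
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                bpp = beta.copy(); bpp[i] += eps; bpp[j] += eps
                bpm = beta.copy(); bpm[i] += eps; bpm[j] -= eps
                bmp = beta.copy(); bmp[i] -= eps; bmp[j] += eps
                bmm = beta.copy(); bmm[i] -= eps; bmm[j] -= eps
                H[i, j] = (ll(bpp) - ll(bpm) - ll(bmp) + ll(bmm)) / (4 * eps**2)
        np.testing.assert_allclose(
            sm.variance_model_based(fit, X, w), np.linalg.inv(-H), rtol=1e-5
        )

    def test_sandwich_invariant_to_weight_rescaling(self, rng):
        n = 250
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        w = rng.uniform(1, 10, n)
        fit = sm.fit_logistic(y, X, weights=w)
        v1 = sm.variance_sandwich(fit, y, X, w)
        v2 = sm.variance_sandwich(fit, y, X, 13.0 * w)
        np.testing.assert_allclose(v1, v2, rtol=1e-10)

    def test_sandwich_matches_statsmodels_hc0(self, rng):
        n = 300
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n),
                          "g": (rng.random(n) < 0.4).astype(float)})
        y = (rng.random(n) < expit(-0.5 + 0.8 * X.x)).astype(float)
        w = rng.uniform(1, 5, n)
        fit = sm.fit_logistic(y, X, weights=w)
        ref = smapi.GLM(y, X, family=smapi.families.Binomial(), var_weights=w).fit(
            cov_type="HC0"
        )
        np.testing.assert_allclose(
            sm.variance_sandwich(fit, y, X, w), ref.cov_params().values, atol=1e-10
        )

    def test_sandwich_near_information_when_model_correct(self):
        # equal weights + correctly specified model: the information identity
        # makes the two variance estimates agree asymptotically
        rng = np.random.default_rng(99)
        n = 10_000
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float)])
        y = (rng.random(n) < expit(-0.4 + 0.9 * X[:, 1])).astype(float)
        w = np.ones(n)
        fit = sm.fit_logistic(y, X, weights=w)
        s = np.sqrt(np.diag(sm.variance_sandwich(fit, y, X, w)))
        m = np.sqrt(np.diag(sm.variance_model_based(fit, X, w)))
        assert np.all(np.abs(s / m - 1) < 0.05)

    def test_stratified_sandwich_matches_explicit_loops(self, rng):
        n = 200
        strata = np.repeat(np.arange(4), n // 4)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.45).astype(float)
        w = rng.uniform(1, 6, n)
        fit = sm.fit_logistic(y, X, weights=w)
        V = sm.variance_sandwich(fit, y, X, w, strata=strata)
        # independent plodding reimplementation
        p = expit(X @ fit.coefficients.values)
        A = sum(w[i] * p[i] * (1 - p[i]) * np.outer(X[i], X[i]) for i in range(n))
        B = np.zeros((2, 2))
        for h in range(4):
            idx = np.flatnonzero(strata == h)
            u = np.array([w[i] * (y[i] - p[i]) * X[i] for i in idx])
            uc = u - u.mean(axis=0)
            B += len(idx) / (len(idx) - 1) * (uc.T @ uc)
        Ainv = np.linalg.inv(A)
        np.testing.assert_allclose(V, Ainv @ B @ Ainv, rtol=1e-8)

    def test_single_unit_stratum_rejected(self, rng):
        n = 21
        strata = np.r_[np.zeros(20), [1]]
        X = np.column_stack([np.ones(n)])
        y = (rng.random(n) < 0.5).astype(float)
        fit = sm.fit_logistic(y, X)
        with pytest.raises(SingleUnitStratumError):
            sm.variance_sandwich(fit, y, X, np.ones(n), strata=strata)


@pytest.fixture(scope="module")
def pop_and_sample(small_pop):
    overall, _ = sm.empirical_matrices()
    pop = sm.apply_misclassification(small_pop, overall, np.random.default_rng(55))
    sample = sm.dss(pop, [200] * 5, np.random.default_rng(56))
    return pop, sample


class TestFitMethod:
    def test_wald_interval_width(self, pop_and_sample):
        pop, sample = pop_and_sample
        fit = sm.fit_method(pop, sample, sm.ModelSpec("design_based"))
        width = fit.ci_upper - fit.ci_lower
        np.testing.assert_allclose(width.values, 2 * norm.ppf(0.975) * fit.se.values,
                                   atol=1e-12)

    def test_model_based_includes_recorded_dummies(self, pop_and_sample):
        pop, sample = pop_and_sample
        fit = sm.fit_method(pop, sample, sm.ModelSpec("model_based"))
        assert "recorded_Hispanic" in fit.coefficients.index
        agnostic = sm.fit_method(pop, sample, sm.ModelSpec("design_agnostic"))
        assert "recorded_Hispanic" not in agnostic.coefficients.index

    def test_design_based_on_self_weighting_sample_equals_agnostic(self, small_pop):
        sample = sm.srs(small_pop, 3000, np.random.default_rng(57))
        dz = sm.fit_method(small_pop, sample, sm.ModelSpec("design_agnostic"))
        db = sm.fit_method(small_pop, sample, sm.ModelSpec("design_based"))
        np.testing.assert_allclose(
            dz.coefficients.values, db.coefficients.values, atol=1e-9
        )
        assert db.variance_method == "sandwich"

    def test_full_cohort_aggregated_fit_equals_unit_level(self, small_pop):
        fit = sm.fit_method(small_pop, None, sm.ModelSpec("design_agnostic"))
        y, X, names = _design_frame(small_pop, None, False)
        ref = sm.fit_logistic(y, pd.DataFrame(X, columns=names))
        np.testing.assert_allclose(
            fit.coefficients.values, ref.coefficients.values, atol=1e-9
        )
        np.testing.assert_allclose(fit.se.values, ref.se.values, atol=1e-9)

    def test_absent_category_dummy_dropped(self, rng):
        cfg = sm.PopulationConfig(N=4000, race_probs=(0.6, 0.4, 0.0, 0.0, 0.0))
        pop = sm.generate_population(cfg, 60)
        fit = sm.fit_method(pop, None, sm.ModelSpec("design_agnostic"))
        assert "Asian" in fit.dropped_terms
        assert "Asian" not in fit.coefficients.index

    def test_full_cohort_design_based_rejected(self, small_pop):
        with pytest.raises(ValueError, match="design_based"):
            sm.fit_method(small_pop, None, sm.ModelSpec("design_based"))

    def test_fit_result_serialization(self, pop_and_sample):
        import json

        pop, sample = pop_and_sample
        fit = sm.fit_method(pop, sample, sm.ModelSpec("design_based"))
        blob = json.loads(fit.to_json())
        assert blob["variance_method"] == "sandwich"
        assert blob["coefficients"]["Hispanic"] == pytest.approx(
            fit.coefficients["Hispanic"]
        )
        rows = fit.to_csv_row(scenario="s", method="design_based")
        assert list(rows.columns) == [
            "scenario", "method", "parameter", "estimate", "se",
            "ci_lower", "ci_upper", "converged",
        ]
        assert len(rows) == len(fit.coefficients)
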