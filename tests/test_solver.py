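"""l1 solver correctness: closed forms, KKT certificates, objective
oracles, and cross-checks against an independent implementation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrinet.solver import (fit_nodewise, kkt_violation, lambda_grid,
                            lambda_max, objective, standardize)

KKT_TOL = 1e-6


def _standardize_unit_gram(x):
    """Center and scale so that x'x/n = 1 exactly."""
    x = x - x.mean()
    return x / np.sqrt((x**2).mean())


class TestStandardize:
    def test_hand_example(self):
        out, centers, scales = standardize(np.array([[1.0], [2.0], [3.0]]), ["continuous"])
        assert np.allclose(out.ravel(), [-1, 0, 1])
        assert centers[0] == 2 and scales[0] == 1

    def test_binary_passes_through(self):
        col = np.array([[0.0], [1.0], [1.0], [0.0]])
        out, _, _ = standardize(col, ["binary"])
        assert np.array_equal(out, col)

    def test_constant_column_errors_with_name(self):
        with pytest.raises(ValueError, match="widgets"):
            standardize(np.full((3, 1), 5.0), ["continuous"], ["widgets"])

    def test_non01_binary_errors(self):
        with pytest.raises(ValueError, match="0/1"):
            standardize(np.array([[0.0], [2.0]]), ["binary"])

    def test_moments(self, rng):
        X = rng.normal(3, 2, size=(50, 3))
        out, _, _ = standardize(X, ["continuous"] * 3)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1)


class TestLambdaGrid:
    def test_lambda_max_closed_form(self, rng):
        x = _standardize_unit_gram(rng.standard_normal(100))
        y = 0.8 * x + 0.0  # x'y/n = 0.8 exactly
        assert lambda_max(x[:, None], y, "gaussian") == pytest.approx(0.8)

    def test_two_point_grid(self, rng):
        x = _standardize_unit_gram(rng.standard_normal(50))
        grid = lambda_grid(x[:, None], x, "gaussian", n_lambda=2, min_ratio=0.01)
        assert grid[0] == pytest.approx(lambda_max(x[:, None], x, "gaussian"))
        assert grid[1] == pytest.approx(grid[0] * 0.01)

    def test_constant_response_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            lambda_grid(rng.standard_normal((20, 2)), np.ones(20), "gaussian")

    def test_all_zero_at_lambda_max(self, rng):
        X = rng.standard_normal((80, 6))
        y = X[:, 0] + rng.standard_normal(80)
        lmax = lambda_max(X, y, "gaussian")
        fit = fit_nodewise(X, y, "gaussian", lmax * (1 + 1e-12))
        assert np.all(fit.coefficients == 0)


class TestGaussianFit:
    def test_univariate_soft_threshold(self, rng):
        x = _standardize_unit_gram(rng.standard_normal(200))
        y = x.copy()  # x'y/n = 1.0
        fit = fit_nodewise(x[:, None], y, "gaussian", 0.4)
        assert fit.coefficients[0] == pytest.approx(0.6, abs=1e-8)

    def test_lambda_zero_matches_least_squares(self, rng):
        X = rng.standard_normal((100, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(100)
        fit = fit_nodewise(X, y, "gaussian", 0.0)
        Xd = np.column_stack([np.ones(100), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.allclose(np.r_[fit.intercept, fit.coefficients], ols, atol=1e-6)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_nodewise(rng.standard_normal((10, 2)), rng.standard_normal(10),
                         "gaussian", -0.1)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_kkt_certificate(self, rng, family):
        X = rng.standard_normal((150, 8))
        if family == "gaussian":
            y = X[:, 0] - 0.5 * X[:, 1] + rng.standard_normal(150)
        else:
            eta = 0.5 + X[:, 0] - 0.5 * X[:, 1]
            y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(float)
        for lam in (0.0, 0.01, 0.05, 0.2):
            fit = fit_nodewise(X, y, family, lam)
            assert fit.kkt_violation < KKT_TOL, (family, lam)


class TestObjectiveOracle:
    """A dense grid search over coefficient space never beats the solver."""

    @pytest.mark.parametrize("p,lam", [(1, 0.1), (2, 0.05), (3, 0.1)])
    def test_brute_force_cannot_beat_solver(self, rng, p, lam):
        X = rng.standard_normal((60, p))
        y = X @ rng.uniform(-0.8, 0.8, p) + 0.3 * rng.standard_normal(60)
        fit = fit_nodewise(X, y, "gaussian", lam)
        best = objective(X, y, "gaussian", fit.intercept, fit.coefficients, lam)
        # coarse global scan to locate the basin
        coarse_step = 0.05 if p < 3 else 0.1
        coarse_axes = [np.arange(-1.2, 1.2 + 1e-9, coarse_step)] * p
        coarse_best, coarse_beta = np.inf, None
        for beta in itertools.product(*coarse_axes):
            beta = np.array(beta)
            b0 = (y - X @ beta).mean()  # optimal intercept given beta
            val = objective(X, y, "gaussian", b0, beta, lam)
            if val < coarse_best:
                coarse_best, coarse_beta = val, beta
        # dense step-1e-3 search around both candidates
        for center in (fit.coefficients, coarse_beta):
            axes = [np.arange(c - 0.01, c + 0.01 + 1e-12, 1e-3) for c in center]
            for beta in itertools.product(*axes):
                beta = np.array(beta)
                b0 = (y - X @ beta).mean()
                val = objective(X, y, "gaussian", b0, beta, lam)
                assert val > best - 1e-5

    def test_binomial_objective_oracle_1d(self, rng):
        x = rng.standard_normal(80)
        y = (rng.random(80) < 1 / (1 + np.exp(-x))).astype(float)
        lam = 0.05
        fit = fit_nodewise(x[:, None], y, "binomial", lam)
        best = objective(x[:, None], y, "binomial", fit.intercept, fit.coefficients, lam)
        for beta in np.arange(-2, 2 + 1e-9, 1e-3):
            for b0 in np.arange(-0.5, 0.5 + 1e-9, 0.05):
                val = objective(x[:, None], y, "binomial", b0, np.array([beta]), lam)
                assert val > best - 1e-5


class TestCrossCheck:
    """Independent oracle: scikit-learn solves the same objectives."""

    def test_gaussian_matches_sklearn_lasso(self, rng):
        from sklearn.linear_model import Lasso

        X = rng.standard_normal((120, 6))
        y = X @ np.array([1.0, -0.5, 0, 0, 0.3, 0]) + rng.standard_normal(120)
        lam = 0.08
        fit = fit_nodewise(X, y, "gaussian", lam)
        sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100000).fit(X, y)
        assert np.allclose(fit.coefficients, sk.coef_, atol=1e-6)
        assert fit.intercept == pytest.approx(sk.intercept_, abs=1e-6)

    def test_binomial_matches_sklearn_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.standard_normal((300, 5))
        eta = 0.4 + X @ np.array([1.0, -0.7, 0, 0, 0.2])
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        lam = 0.02
        fit = fit_nodewise(X, y, "binomial", lam)
        sk = LogisticRegression(l1_ratio=1.0, C=1.0 / (300 * lam), solver="saga",
                                tol=1e-12, max_iter=200_000).fit(X, y)
        assert np.allclose(fit.coefficients, sk.coef_.ravel(), atol=1e-4)
        assert fit.intercept == pytest.approx(float(sk.intercept_[0]), abs=1e-4)


class TestPathMonotonicity:
    def test_active_set_shrinks_with_lambda(self, rng):
        X = rng.standard_normal((200, 10))
        y = X @ np.array([1, -0.8, 0.6, 0.4, -0.3, 0, 0, 0, 0, 0.0]) \
            + rng.standard_normal(200)
        grid = lambda_grid(X, y, "gaussian", n_lambda=30, min_ratio=1e-3)
        sizes = [np.count_nonzero(fit_nodewise(X, y, "gaussian", lam).coefficients)
                 for lam in grid]
        # grid is descending in lambda, so active sets grow along it
        assert all(a <= b for a, b in zip(sizes[:-1], sizes[1:]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 0.5),
       p=st.integers(1, 6))
def test_kkt_property_random_instances(seed, lam, p):
    """Every gaussian fit satisfies the subgradient conditions."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((50, p))
    y = rng.standard_normal(50)
    fit = fit_nodewise(X, y, "gaussian", lam)
    assert kkt_violation(X, y, "gaussian", fit.intercept, fit.coefficients, lam) < KKT_TOL
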