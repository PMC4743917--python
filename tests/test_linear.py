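"""Linear-regression AR: ridge step, fixed points, paths, shrinkage."""

import numpy as np
import pytest

from conftest import orthonormal_design
from l0ridge.core import ARConfig
from l0ridge.linear import (
    LinearProblem,
    ar_fit,
    ar_fit_restarts,
    ar_path,
    default_lambda_grid,
    l0_equivalent_penalty,
    orthogonal_fixed_point,
    standardize,
    weighted_ridge_solve,
)
from l0ridge.selection import CriterionSpec, all_subset_select, evaluate_criterion


def scalar_ar_limit(beta_hat, n, sigma2, lam_tilde, delta=1e-5, max_iter=10_000_000):
    """Independent scalar oracle: iterate beta <- n beta_hat / (n + lt s2 w)."""
    beta = beta_hat
    for _ in range(max_iter):
        w = 1.0 / (beta**2 + delta**2)
        new = n * beta_hat / (n + lam_tilde * sigma2 * w)
        if abs(new - beta) < 1e-15:
            return new
        beta = new
    return beta


class TestStandardize:
    def test_column_scaling_hand_computed(self):
        X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]])
        y = np.array([1.0, 1.0, 1.0])
        prob = standardize(X, y)
        s = np.sqrt(1.5)
        assert np.allclose(prob.X[:, 0], [-s, 0.0, s])
        assert np.allclose(np.einsum("ij,ij->j", prob.X, prob.X), prob.n)
        assert np.allclose(prob.y, 0.0)

    def test_idempotent(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        p1 = standardize(X, y)
        p2 = standardize(p1.X, p1.y)
        assert np.allclose(p1.X, p2.X)
        assert np.allclose(p1.y, p2.y)

    def test_zero_variance_column_names_offender(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="column 1"):
            standardize(X, rng.standard_normal(10))


class TestWeightedRidgeSolve:
    def test_zero_weights_recover_ols(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        prob = LinearProblem(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta = weighted_ridge_solve(prob, 5.0, np.zeros(4))
        assert np.allclose(beta, ols, atol=1e-10)

    def test_hand_solved_two_point_problem(self):
        prob = LinearProblem(np.array([[1.0], [1.0]]), np.array([0.0, 2.0]))
        beta = weighted_ridge_solve(prob, 2.0, np.array([1.0]))
        assert beta[0] == pytest.approx(2.0 / 4.0)

    def test_huge_penalty_shrinks_to_zero(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        prob = LinearProblem(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta = weighted_ridge_solve(prob, 1e12, np.ones(4))
        assert np.linalg.norm(beta) < 1e-6 * np.linalg.norm(ols)

    def test_singular_system_raises(self, rng):
        X = rng.standard_normal((3, 5))  # p > n, unpenalized
        prob = LinearProblem(X, rng.standard_normal(3))
        with pytest.raises(np.linalg.LinAlgError):
            weighted_ridge_solve(prob, 0.0, np.zeros(5))


class TestOrthogonalFixedPoint:
    def test_retained_coordinate_closed_form(self):
        val = orthogonal_fixed_point(0.5, 100, 1.0, 1.0)
        assert val == pytest.approx((0.5 + np.sqrt(0.21)) / 2.0, abs=1e-12)
        assert val == pytest.approx(0.47913, abs=5e-6)

    def test_matches_scalar_iteration_oracle(self):
        for bh, lt in [(0.5, 1.0), (-0.8, 2.0), (0.3, 1.0), (1.2, 5.0), (0.1, 1.0)]:
            closed = orthogonal_fixed_point(bh, 100, 1.0, lt)
            iterated = scalar_ar_limit(bh, 100, 1.0, lt)
            assert closed == pytest.approx(iterated, abs=1e-6)

    def test_boundary_double_root(self):
        n, s2, lt = 100, 1.0, 1.0
        bh = np.sqrt(4 * lt * s2 / n)
        assert orthogonal_fixed_point(bh, n, s2, lt) == pytest.approx(bh / 2)

    def test_zero_penalty_returns_ols(self):
        assert orthogonal_fixed_point(0.7, 50, 1.0, 0.0) == 0.7


class TestARFit:
    def test_orthonormal_design_retained_and_dropped(self, rng):
        n = 100
        X = orthonormal_design(n, 4, rng)
        bh = np.array([0.5, 0.15, -0.6, 0.01])
        prob = LinearProblem(X, X @ bh)
        fit = ar_fit(prob, 1.0)
        # threshold 4*lt*s2/n = 0.04: coords 0 and 2 survive
        assert fit.support.tolist() == [True, False, True, False]
        expected = orthogonal_fixed_point(bh, n, 1.0, 1.0)
        assert np.allclose(fit.state.beta, expected, atol=1e-6)

    def test_zero_penalty_is_ols_with_full_support(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.standard_normal(40)
        prob = LinearProblem(X, y)
        fit = ar_fit(prob, 0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.state.beta, ols, atol=1e-8)
        assert fit.support.all()

    def test_refit_zero_off_support_and_rss_below_null(self, rng):
        X = rng.standard_normal((50, 6))
        y = X[:, 0] + rng.standard_normal(50)
        prob = standardize(X, y)
        fit = ar_fit(prob, 1.0)
        assert np.all(fit.beta_refit[~fit.support] == 0.0)
        assert fit.rss <= float(prob.y @ prob.y) + 1e-12

    def test_forced_in_coordinate_always_selected(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)  # pure noise
        prob = standardize(X, y)
        cfg = ARConfig(init_weights=np.array([0.0, 1.0, 1.0, 1.0]))
        fit = ar_fit(prob, 20.0, cfg)
        assert fit.support[0]
        assert fit.state.weights[0] == 0.0

    def test_iterates_bounded_by_ols_norm(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 8))
            y = r.standard_normal(40)
            prob = LinearProblem(X, y)
            fit = ar_fit(prob, 2.0, record_history=True)
            ols_norm = np.linalg.norm(np.linalg.lstsq(X, y, rcond=None)[0])
            norms = np.linalg.norm(fit.history["beta"], axis=1)
            assert np.all(norms <= ols_norm + 1e-9)

    def test_orthonormal_shrinkage(self, rng):
        n = 80
        X = orthonormal_design(n, 6, rng)
        bh = rng.normal(0, 0.5, 6)
        prob = LinearProblem(X, X @ bh)
        fit = ar_fit(prob, 1.0)
        assert np.all(np.abs(fit.state.beta) <= np.abs(bh) + 1e-9)

    def test_absorbing_zeros(self, rng):
        # once an indicator has fallen below 1e-4 it never re-crosses 1/2
        X = rng.standard_normal((50, 10))
        y = X[:, :3] @ np.array([0.6, 0.4, -0.5]) + rng.standard_normal(50)
        prob = standardize(X, y)
        fit = ar_fit(prob, np.log(50) / 4, record_history=True)
        ind = fit.history["indicators"]
        for j in range(ind.shape[1]):
            low = np.flatnonzero(ind[:, j] < 1e-4)
            if low.size:
                assert np.all(ind[low[0]:, j] <= 0.5)

    def test_converged_indicator_sum_approximates_support_size(self, rng):
        n = 100
        X = orthonormal_design(n, 5, rng)
        bh = np.array([0.5, 0.7, -0.6, 0.01, 0.02])
        prob = LinearProblem(X, X @ bh)
        fit = ar_fit(prob, 1.0)
        k = int(fit.support.sum())
        bmin = np.abs(fit.state.beta[fit.support]).min()
        assert abs(float(fit.state.indicators.sum()) - k) <= k * (1e-5 / bmin) ** 2 + 1e-9

    def test_restarts_never_worse_than_default(self, rng):
        X = rng.standard_normal((60, 12))
        y = X[:, :4] @ rng.normal(0, 0.6, 4) + rng.standard_normal(60)
        prob = standardize(X, y)
        lt = np.log(60) / 4
        base = ar_fit(prob, lt)
        best = ar_fit_restarts(prob, lt, n_restarts=5, rng=np.random.default_rng(1))
        score = lambda f: f.rss + 4 * lt * f.support.sum()
        assert score(best) <= score(base) + 1e-9


class TestPenaltyMapping:
    def test_bic_penalty_rescaling(self):
        assert l0_equivalent_penalty(np.log(50)) == pytest.approx(0.97801, abs=5e-6)

    def test_trivial_values(self):
        assert l0_equivalent_penalty(0.0) == 0.0
        assert l0_equivalent_penalty(2.0) == 0.5


class TestPath:
    def test_single_element_grid_matches_ar_fit(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + rng.standard_normal(40)
        prob = standardize(X, y)
        path = ar_path(prob, np.array([1.0]))
        direct = ar_fit(prob, 1.0)
        assert np.array_equal(path.fits[0].support, direct.support)
        assert np.allclose(path.fits[0].state.beta, direct.state.beta)

    def test_large_penalty_end_empties_support(self, rng):
        X = rng.standard_normal((50, 6))
        y = X[:, :2] @ np.array([0.5, -0.5]) + rng.standard_normal(50)
        prob = standardize(X, y)
        path = ar_path(prob, default_lambda_grid(prob, num=25))
        sizes = [int(f.support.sum()) for f in path.fits]
        assert sizes[-1] == 0
        assert sizes[-1] == min(sizes)

    def test_decreasing_grid_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        prob = standardize(X, rng.standard_normal(20))
        with pytest.raises(ValueError):
            ar_path(prob, np.array([2.0, 1.0]))

    def test_warm_start_matches_cold_start_on_orthogonal_design(self, rng):
        n = 60
        X = orthonormal_design(n, 5, rng)
        y = X @ np.array([0.6, 0.3, 0.0, -0.5, 0.1]) + 0.3 * rng.standard_normal(n)
        prob = LinearProblem(X, y)
        grid = default_lambda_grid(prob, num=15)
        path = ar_path(prob, grid)
        spec = CriterionSpec("bic")
        for i in (4, 9, 14):
            warm = evaluate_criterion(prob, path.fits[i].support, spec).criterion_value
            cold_fit = ar_fit(prob, float(grid[i]))
            cold = evaluate_criterion(prob, cold_fit.support, spec).criterion_value
            assert warm == pytest.approx(cold, abs=1e-6)


class TestOrthogonalL0Equivalence:
    def test_ar_support_matches_exact_l0_and_all_subset(self, rng):
        n, p = 100, 8
        X = orthonormal_design(n, p, rng)
        bh = np.array([0.05, 0.1, 0.18, 0.25, 0.4, 0.6, -0.35, -0.15])
        prob = LinearProblem(X, X @ bh)
        lam_bic = np.log(n)
        lt = l0_equivalent_penalty(lam_bic)
        fit = ar_fit(prob, lt)
        hard = bh**2 > 4 * lt / n
        assert np.array_equal(fit.support, hard)
        exact = all_subset_select(prob, CriterionSpec("bic"))
        assert np.array_equal(fit.support_indices, exact.support)
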