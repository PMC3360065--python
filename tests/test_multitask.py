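import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import ortho_group

from sirnarank.multitask import (SolverConfig, StackedDesign, assign_folds,
                                 cv_fit, fit_multitask, lambda_max, penalty,
                                 project_l1_ball, prox_l1inf, prox_l21,
                                 prox_trace, select_lambda,
                                 squared_loss_and_gradient)


def rand_design(seed=0, d=8, sizes=(20, 15)):
    rng = np.random.default_rng(seed)
    X = [rng.standard_normal((n, d)) for n in sizes]
    for Xj in X:
        Xj[:, 0] = 1.0
    y = [rng.standard_normal(n) for n in sizes]
    return StackedDesign(X, y)


class TestLossAndGradient:
    def test_interpolating_solution_has_zero_loss(self):
        rng = np.random.default_rng(0)
        Xj = rng.standard_normal((5, 5)) + np.eye(5)
        w = rng.standard_normal(5)
        design = StackedDesign([Xj], [Xj @ w])
        loss, grad = squared_loss_and_gradient(w[:, None], design)
        assert loss == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(grad, 0.0, atol=1e-12)

    def test_zero_everything(self):
        design = StackedDesign([np.ones((3, 2))], [np.zeros(3)])
        loss, _ = squared_loss_and_gradient(np.zeros((2, 1)), design)
        assert loss == 0.0

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        design = StackedDesign([rng.standard_normal((5, 3))],
                               [rng.standard_normal(5)])
        W = rng.standard_normal((3, 1))
        loss, grad = squared_loss_and_gradient(W, design)
        eps = 1e-6
        for i in range(3):
            Wp, Wm = W.copy(), W.copy()
            Wp[i, 0] += eps
            Wm[i, 0] -= eps
            num = (squared_loss_and_gradient(Wp, design)[0]
                   - squared_loss_and_gradient(Wm, design)[0]) / (2 * eps)
            assert grad[i, 0] == pytest.approx(num, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        design = rand_design()
        with pytest.raises(ValueError):
            squared_loss_and_gradient(np.zeros((3, 2)), design)


class TestPenalty:
    def test_zero_matrix(self):
        W = np.zeros((4, 3))
        assert all(penalty(W, n) == 0.0 for n in ("l21", "l1inf", "trace"))

    def test_diagonal_matrix_hand_values(self):
        W = np.diag([3.0, 4.0])
        assert penalty(W, "l21") == pytest.approx(7.0)
        assert penalty(W, "l1inf") == pytest.approx(7.0)
        assert penalty(W, "trace") == pytest.approx(7.0)

    def test_single_row_hand_values(self):
        W = np.array([[3.0, 4.0], [0.0, 0.0]])
        assert penalty(W, "l21") == pytest.approx(5.0)
        assert penalty(W, "l1inf") == pytest.approx(4.0)


class TestProxOperators:
    def test_l21_row_scaling(self):
        row = np.array([[3.0, 4.0]])  # norm 5, t=2 -> scale 3/5
        assert np.allclose(prox_l21(row, 2.0), row * 0.6)

    def test_l21_kills_small_rows(self):
        assert np.allclose(prox_l21(np.array([[0.3, 0.4]]), 1.0), 0.0)

    def test_l1inf_hand_example(self):
        out = prox_l1inf(np.array([[3.0, 1.0]]), 1.0)
        assert np.allclose(out, [[2.0, 1.0]])

    def test_l1inf_kills_small_rows(self):
        assert np.allclose(prox_l1inf(np.array([[0.4, -0.3]]), 1.0), 0.0)

    def test_trace_diagonal(self):
        out = prox_trace(np.diag([3.0, 1.0]), 1.0)
        assert np.allclose(out, np.diag([2.0, 0.0]), atol=1e-12)

    def test_trace_full_shrinkage(self):
        V = np.diag([3.0, 1.0])
        assert np.allclose(prox_trace(V, 3.5), 0.0, atol=1e-12)

    @pytest.mark.parametrize("prox", [prox_l21, prox_l1inf, prox_trace])
    def test_t_zero_is_identity(self, prox):
        V = np.random.default_rng(3).standard_normal((4, 3))
        assert np.allclose(prox(V, 0.0), V)

    @pytest.mark.parametrize("prox", [prox_l21, prox_l1inf, prox_trace])
    @pytest.mark.parametrize("seed", range(5))
    def test_non_expansive(self, prox, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.standard_normal((2, 6, 4))
        t = float(rng.uniform(0.1, 2.0))
        assert (np.linalg.norm(prox(A, t) - prox(B, t))
                <= np.linalg.norm(A - B) + 1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_l1_projection_matches_bisection_oracle(self, seed):
        """Independent dual-bisection oracle for the ℓ1-ball projection."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(6) * 3
        radius = float(rng.uniform(0.5, 3.0))
        ours = project_l1_ball(v, radius)
        if np.abs(v).sum() <= radius:
            assert np.allclose(ours, v)
            return
        theta = brentq(lambda th: np.maximum(np.abs(v) - th, 0).sum() - radius,
                       0.0, np.abs(v).max(), xtol=1e-14)
        oracle = np.sign(v) * np.maximum(np.abs(v) - theta, 0)
        assert np.allclose(ours, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_l21_matches_scalar_solver_oracle(self, seed):
        """The prox reduces to a 1-D problem along each row's direction;
        solve that restriction with a generic bounded scalar optimiser."""
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((4, 3)) * 2
        t = float(rng.uniform(0.2, 1.5))
        ours = prox_l21(V, t)
        for row, ours_row in zip(V, ours):
            nrm = np.linalg.norm(row)
            res = minimize_scalar(
                lambda c: 0.5 * (c - 1) ** 2 * nrm**2 + t * abs(c) * nrm,
                bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-12})
            assert np.allclose(ours_row, res.x * row, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_l1inf_prox_matches_moreau_oracle(self, seed):
        """Moreau identity with the independent bisection projection."""
        rng = np.random.default_rng(40 + seed)
        V = rng.standard_normal((4, 3)) * 2
        t = float(rng.uniform(0.2, 1.5))
        ours = prox_l1inf(V, t)
        for row, ours_row in zip(V, ours):
            if np.abs(row).sum() <= t:
                assert np.allclose(ours_row, 0.0)
                continue
            theta = brentq(
                lambda th: np.maximum(np.abs(row) - th, 0).sum() - t,
                0.0, np.abs(row).max(), xtol=1e-14)
            proj = np.sign(row) * np.maximum(np.abs(row) - theta, 0)
            assert np.allclose(ours_row, row - proj, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_prox_matches_constructed_svd_oracle(self, seed):
        """Matrices built from known orthogonal factors and singular values
        have a closed-form answer independent of the implementation's SVD."""
        rng = np.random.default_rng(seed)
        U = ortho_group.rvs(4, random_state=seed)[:, :3]
        Vt = ortho_group.rvs(3, random_state=seed + 100)
        s = np.sort(rng.uniform(0.2, 3.0, 3))[::-1]
        M = (U * s) @ Vt
        t = float(s[1])  # threshold between singular values
        expected = (U * np.maximum(s - t, 0.0)) @ Vt
        assert np.allclose(prox_trace(M, t), expected, atol=1e-5)


class TestFitMultitask:
    def test_full_shrinkage_above_lambda_max(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        for norm in ("l21", "l1inf", "trace"):
            lmax = lambda_max(design, norm)
            fit = fit_multitask(design, SolverConfig(norm=norm, lam=1.01 * lmax))
            assert fit.support().size == 0

    def test_lambda_zero_single_task_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 5))
        X[:, 0] = 1.0
        y = rng.standard_normal(40)
        design = StackedDesign([X], [y])
        fit = fit_multitask(design, SolverConfig(norm="l21", lam=0.0, tol=1e-12,
                                                 max_iter=50_000))
        w_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.W[:, 0], w_ols, atol=1e-5)

    def test_objective_trace_monotone_non_increasing(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        for norm in ("l21", "l1inf", "trace"):
            fit = fit_multitask(design, SolverConfig(norm=norm, lam=0.05))
            assert np.all(np.diff(fit.objective_trace) <= 1e-12)

    def test_optimal_objective_monotone_in_lambda(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        objs = []
        for lam in (0.01, 0.05, 0.2):
            fit = fit_multitask(design, SolverConfig(norm="l21", lam=lam))
            loss, _ = squared_loss_and_gradient(fit.W, design)
            objs.append(loss + lam * penalty(fit.W[1:], "l21"))
        assert objs[0] <= objs[1] <= objs[2]

    def test_recovers_planted_support(self, small_gaussian_design):
        design, support, _ = small_gaussian_design
        lmax = lambda_max(design, "l21")
        fit = fit_multitask(design, SolverConfig(norm="l21", lam=0.1 * lmax))
        assert set(fit.support()) == set(support)

    def test_matches_long_run_reference(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        lam = 0.05
        short = fit_multitask(design, SolverConfig(norm="l21", lam=lam, tol=1e-8))
        long = fit_multitask(design, SolverConfig(norm="l21", lam=lam, tol=1e-13,
                                                  max_iter=100_000))
        def obj(W):
            loss, _ = squared_loss_and_gradient(W, design)
            return loss + lam * penalty(W[1:], "l21")
        assert obj(short.W) <= obj(long.W) + 1e-6


class TestCrossValidation:
    def test_noise_free_tasks_have_tiny_rmse(self):
        rng = np.random.default_rng(11)
        d = 10
        w = rng.standard_normal((d, 2)) * 0.2
        X = [rng.standard_normal((60, d)) for _ in range(2)]
        for Xj in X:
            Xj[:, 0] = 1.0
        design = StackedDesign([Xj for Xj in X], [X[j] @ w[:, j] for j in range(2)])
        cv = cv_fit(design, SolverConfig(norm="l21", lam=1e-8, tol=1e-12,
                                         max_iter=50_000), folds=4, seed=0)
        assert np.nanmax(cv.rmse) < 1e-3

    def test_null_model_rmse_equals_heldout_deviation(self):
        """At λ ≥ λ_max only the intercept survives: the prediction is the
        training mean, so RMSE equals held-out deviation around it."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 4))
        X[:, 0] = 1.0
        y = rng.standard_normal(20)
        design = StackedDesign([X], [y])
        lmax = lambda_max(design, "l21")
        folds = 2
        labels = assign_folds(design, folds, seed=5)[0]
        cv = cv_fit(design, SolverConfig(norm="l21", lam=2 * lmax), folds=folds,
                    seed=5)
        for f in range(folds):
            tr, te = y[labels != f], y[labels == f]
            expected = np.sqrt(np.mean((te - tr.mean()) ** 2))
            assert cv.rmse[f, 0] == pytest.approx(expected, rel=1e-6)

    def test_fold_assignment_reproducible(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        a = assign_folds(design, 10, seed=9)
        b = assign_folds(design, 10, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_tiny_task_gets_leave_one_out_folds(self):
        rng = np.random.default_rng(0)
        X = [rng.standard_normal((30, 4)), rng.standard_normal((5, 4))]
        y = [rng.standard_normal(30), rng.standard_normal(5)]
        design = StackedDesign(X, y)
        labels = assign_folds(design, 10, seed=1)
        assert sorted(labels[1]) == [0, 1, 2, 3, 4]  # each record its own fold

    def test_select_lambda_reproducible(self, small_gaussian_design):
        design, _, _ = small_gaussian_design
        lam1, grid1, _ = select_lambda(design, "l21", folds=4, seed=2, n_points=6)
        lam2, grid2, _ = select_lambda(design, "l21", folds=4, seed=2, n_points=6)
        assert lam1 == lam2 and np.array_equal(grid1, grid2)
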