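import numpy as np
import pytest
import scipy.optimize
import scipy.sparse.linalg

import dbtrecon as d
from dbtrecon.regularization import tv_beta_gradient
from dbtrecon.solvers import (
    BBState,
    CPOptions,
    DegenerateScheduleError,
    LineSearchError,
    MatrixOperator,
    SolverConfig,
    armijo_linesearch,
    auto_lambda1,
    bb_steplength,
    conjugate_gradient,
    cp_dual_ball_prox,
    cp_dual_gradient_prox,
    cp_solve,
    fp_outer_iterations,
    fp_solve,
    lambda_schedule,
    least_squares,
    ls_gradient,
    objective,
    power_method_norm,
    rho_schedule,
    sgp_scaling,
    sgp_solve,
    stopping_criterion,
    tv_gradient_split,
)


class TestObjectivePieces:
    def test_least_squares_at_zero_is_data_norm(self, consistent_problem, small_geom):
        _, b = consistent_problem
        val = least_squares(d.Volume.zeros(small_geom), b, small_geom)
        assert val == pytest.approx(np.sum(b.values**2), rel=1e-12)

    def test_least_squares_exact_fit_is_zero(self, consistent_problem, small_geom):
        x_true, b = consistent_problem
        assert least_squares(x_true, b, small_geom) == pytest.approx(0.0, abs=1e-18)

    def test_ls_gradient_vanishes_at_exact_fit(self, consistent_problem, small_geom):
        x_true, b = consistent_problem
        grad = ls_gradient(x_true, b, small_geom)
        assert np.abs(grad.values).max() < 1e-12

    def test_ls_gradient_at_zero_is_minus_2mtb(self, consistent_problem, small_geom):
        _, b = consistent_problem
        grad = ls_gradient(d.Volume.zeros(small_geom), b, small_geom)
        expected = -2.0 * d.back_project(b).values
        np.testing.assert_allclose(grad.values, expected, atol=1e-14)

    def test_ls_gradient_matches_finite_differences(self, rng):
        op = MatrixOperator(rng.standard_normal((20, 12)), (3, 2, 2), (20,))
        b = rng.standard_normal(20)
        x = rng.standard_normal((3, 2, 2))
        grad = ls_gradient(x, b, op)
        h = 1e-5
        fd = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd[idx] = (least_squares(xp, b, op) - least_squares(xm, b, op)) / (2 * h)
        assert np.abs(grad - fd).max() / np.abs(fd).max() < 1e-6

    def test_objective_composition(self, consistent_problem, small_geom, rng):
        _, b = consistent_problem
        x = d.Volume(rng.uniform(0, 0.1, small_geom.grid_shape), small_geom)
        lam, beta = 0.3, 0.001
        full = objective(x, b, small_geom, lam, beta)
        assert full == least_squares(x, b, small_geom) + lam * d.tv_beta(x.values, beta)
        assert objective(x, b, small_geom, 0.0, beta) == least_squares(x, b, small_geom)
        with pytest.raises(ValueError):
            objective(x, b, small_geom, -1.0, beta)


class TestScaling:
    def test_clip_branches(self):
        x = np.array([[[2.0]], [[0.0]], [[1e6]]])
        v = np.array([[[1.0]], [[1.0]], [[1.0]]])
        s = sgp_scaling(x, v, 10.0)
        np.testing.assert_allclose(s.ravel(), [2.0, 0.1, 10.0])

    def test_nonpositive_v_rejected(self):
        with pytest.raises(ValueError):
            sgp_scaling(np.ones((1, 1, 1)), np.zeros((1, 1, 1)), 10.0)

    def test_tv_split_reconstructs_gradient_and_is_nonnegative(self, rng):
        x = rng.uniform(0, 1, (5, 4, 3))
        beta = 0.01
        v_part, u_part = tv_gradient_split(x, beta)
        assert v_part.min() >= 0 and u_part.min() >= 0
        np.testing.assert_allclose(
            v_part - u_part, tv_beta_gradient(x, beta), atol=1e-12
        )


class TestBBStepLength:
    def test_identity_quadratic_gives_unit_steps(self):
        s = np.array([0.3, -0.7])
        bb1, bb2 = bb_steplength(s, s, np.ones(2))  # grad f = x -> y = s
        assert bb1 == pytest.approx(1.0) and bb2 == pytest.approx(1.0)

    def test_nonpositive_curvature_falls_back_to_alpha_max(self):
        s = np.array([1.0, 0.0])
        y = np.array([-1.0, 0.0])
        bb1, bb2 = bb_steplength(s, y, np.ones(2), alpha_max=1e10)
        assert bb1 == 1e10 and bb2 == 1e10

    def test_diagonal_quadratic_hand_computation(self):
        # f(x) = x^T diag(1,4) x / 2 from x0 = (1,1), exact gradient step
        a = np.array([1.0, 4.0])
        x0 = np.array([1.0, 1.0])
        g0 = a * x0
        alpha = g0 @ g0 / (g0 @ (a * g0))
        s = -alpha * g0
        y = a * s
        bb1, _ = bb_steplength(s, y, np.ones(2))
        assert bb1 == pytest.approx((s @ s) / (s @ y), rel=1e-14)

    def test_alternation_stays_within_bounds(self, rng):
        state = BBState(alpha0=1.0, alpha_min=1e-3, alpha_max=1e3)
        for _ in range(10):
            s = rng.standard_normal(6)
            y = rng.standard_normal(6)
            alpha = state.update(s, y, np.ones(6))
            assert 1e-3 <= alpha <= 1e3


class TestArmijo:
    def test_quadratic_accepts_full_step(self):
        f = lambda z: float(0.5 * np.sum(z**2))  # noqa: E731
        x = np.array([1.0])
        eta, x_new, f_new, n = armijo_linesearch(f, x, np.array([-1.0]), x, f(x), sigma=1e-4)
        assert eta == 1.0 and x_new[0] == 0.0 and n == 0

    def test_quartic_backtracks(self):
        f = lambda z: float(np.sum(z**4))  # noqa: E731
        x = np.array([1.0])
        grad = np.array([4.0])
        eta, _, f_new, n = armijo_linesearch(
            f, x, np.array([-1.0]), grad, f(x), sigma=0.9, gamma_=0.5
        )
        assert eta < 1.0 and n >= 1
        assert f_new <= f(x) + 0.9 * eta * (-4.0)

    def test_sufficient_decrease_postcondition(self, rng):
        f = lambda z: float(np.sum(z**2) + np.sum(np.abs(z) ** 3))  # noqa: E731
        for _ in range(5):
            x = rng.standard_normal(4)
            grad = 2 * x + 3 * np.abs(x) * np.sign(x)
            dvec = -grad
            eta, x_new, f_new, _ = armijo_linesearch(f, x, dvec, grad, f(x))
            assert f_new <= f(x) + 1e-4 * eta * float(grad @ dvec) + 1e-15

    def test_non_descent_direction_rejected(self):
        f = lambda z: float(np.sum(z**2))  # noqa: E731
        with pytest.raises(ValueError):
            armijo_linesearch(f, np.array([1.0]), np.array([1.0]), np.array([2.0]), 1.0)

    def test_exhausted_budget_raises(self):
        f = lambda z: float(np.sum(z**2)) + 10.0  # inconsistent reference value
        with pytest.raises(LineSearchError):
            armijo_linesearch(
                f, np.array([1.0]), np.array([-1.0]), np.array([2.0]), 1.0, max_backtracks=5
            )


class TestConjugateGradient:
    def test_identity_solved_in_one_iteration(self, rng):
        rhs = rng.standard_normal(7)
        out = conjugate_gradient(lambda v: v, rhs, 1)
        np.testing.assert_allclose(out, rhs, atol=1e-14)

    def test_two_eigenvalues_need_two_iterations(self):
        a = np.array([1.0, 2.0])
        rhs = np.array([1.0, 1.0])
        out = conjugate_gradient(lambda v: a * v, rhs, 2)
        np.testing.assert_allclose(out, rhs / a, atol=1e-12)

    def test_matches_direct_solve(self, rng):
        m = rng.standard_normal((5, 5))
        h = m @ m.T + 5 * np.eye(5)
        rhs = rng.standard_normal(5)
        out = conjugate_gradient(lambda v: h @ v, rhs, 5)
        np.testing.assert_allclose(out, np.linalg.solve(h, rhs), atol=1e-8)


class TestSchedules:
    def test_rho_schedule_values(self):
        assert rho_schedule(1) == 1.0 + 1e15
        ks = np.arange(1, 50)
        vals = [rho_schedule(int(k)) for k in ks]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            rho_schedule(0)

    def test_lambda_schedule_arithmetic(self):
        assert lambda_schedule(0) == 0.0
        assert lambda_schedule(4, lambda1=0.1) == pytest.approx(0.025)
        lam1 = 0.37
        for k in range(1, 20):
            assert lambda_schedule(k, lam1) * k == pytest.approx(lam1, rel=1e-15)

    def test_flat_first_iterate_rejected(self, consistent_problem, small_geom):
        _, b = consistent_problem
        flat = d.Volume(np.full(small_geom.grid_shape, 0.3), small_geom)
        with pytest.raises(DegenerateScheduleError):
            auto_lambda1(flat, b.values, small_geom)

    def test_stopping_criterion_cases(self):
        assert stopping_criterion([10.0, 10.0], 1e-6) is True
        assert stopping_criterion([10.0, 9.0], 1e-6) is False  # |df|/f = 1/9
        assert stopping_criterion([1.0, 1.0 - 5e-7], 1e-6) is True
        assert stopping_criterion([1.0, 0.0], 1e-6) is True  # degenerate
        with pytest.raises(ValueError):
            stopping_criterion([1.0], 1e-6)


class TestSGP:
    def test_monotone_objective_and_nonnegative_output(self, textured_fixture, small_geom):
        _, b, _ = textured_fixture
        vol, trace = sgp_solve(b, small_geom, SolverConfig(lambda_=0.005, max_iter=15, tol=0.0))
        assert vol.values.min() >= 0.0
        diffs = np.diff(trace.objective_values)
        assert np.all(diffs <= 1e-10)

    def test_tiny_dense_problem_reaches_nnls_minimizer(self):
        m = np.array([[1.0, 2.0], [3.0, 1.0], [0.5, 0.5]])
        b = np.array([1.0, -0.5, 0.3])  # negative component activates the constraint
        op = MatrixOperator(m, (2, 1, 1), (3,))
        x_ref, _ = scipy.optimize.nnls(m, b)
        x, trace = sgp_solve(b, op, SolverConfig(lambda_=0.0, max_iter=300, tol=0.0))
        np.testing.assert_allclose(x.ravel(), x_ref, atol=1e-6)

    def test_immediate_convergence_from_optimal_start(self):
        m = np.array([[1.0, 2.0], [3.0, 1.0], [0.5, 0.5]])
        b = np.array([1.0, -0.5, 0.3])
        op = MatrixOperator(m, (2, 1, 1), (3,))
        x_ref, _ = scipy.optimize.nnls(m, b)
        _, trace = sgp_solve(
            b, op, SolverConfig(lambda_=0.0, max_iter=50, tol=1e-12), x0=x_ref.reshape(2, 1, 1)
        )
        assert trace.converged and trace.iterations_run <= 5

    def test_auto_schedule_recorded_in_trace(self, textured_fixture, small_geom):
        _, b, _ = textured_fixture
        _, trace = sgp_solve(b, small_geom, SolverConfig(lambda_="auto", max_iter=6, tol=0.0))
        lams = trace.lambda_values
        assert lams[0] == 0.0
        lam1 = lams[1]
        assert lam1 > 0
        for k in range(1, len(lams)):
            assert lams[k] == pytest.approx(lam1 / k, rel=1e-12)


class TestFP:
    def test_iteration_accounting(self):
        assert fp_outer_iterations(15, 4) == 3  # 3 outer x (1 + 4 CG) = 15
        assert fp_outer_iterations(5, 4) == 1

    def test_output_projected_nonnegative(self, textured_fixture, small_geom):
        _, b, _ = textured_fixture
        vol, trace = fp_solve(b, small_geom, SolverConfig(lambda_=0.001, max_iter=3, tol=0.0))
        assert vol.values.min() >= 0.0
        assert trace.accounted_iterations == 3 * (1 + 4)

    def test_lambda_zero_matches_dense_least_squares(self, rng):
        m = rng.standard_normal((30, 8)) + 2.0
        x_true = rng.uniform(0.1, 1.0, 8)
        b = m @ x_true
        op = MatrixOperator(m, (2, 2, 2), (30,))
        x, trace = fp_solve(b, op, SolverConfig(lambda_=0.0, max_iter=20, tol=0.0))
        assert np.linalg.norm(m @ x.ravel() - b) / np.linalg.norm(b) < 1e-6


class TestPowerMethod:
    def test_identity_operator_gives_one(self):
        gamma = power_method_norm(lambda v: v, n_iters=3, seed=0, shape=(2, 2, 2))
        assert gamma == pytest.approx(1.0, rel=1e-12)

    def test_gradient_blocks_bounded_by_sqrt12(self):
        zero_op = MatrixOperator(np.zeros((4, 27)), (3, 3, 3), (4,))
        gamma = power_method_norm(zero_op, n_iters=50, seed=0)
        assert gamma <= np.sqrt(12.0) + 1e-9

    def test_converges_to_dense_singular_value(self, small_geom):
        g = small_geom
        nv = g.n_voxels

        def matvec(v):
            vol = v.reshape(g.grid_shape)
            parts = [d.forward_project(d.Volume(vol, g)).values.ravel()]
            for a in range(3):
                parts.append((np.roll(vol, -1, axis=a) - vol).ravel())
            return np.concatenate(parts)

        def rmatvec(u):
            proj = u[: g.n_data].reshape((g.n_angles, g.detector_rows, g.detector_cols))
            out = d.back_project(d.ProjectionStack(proj, g)).values
            offset = g.n_data
            for a in range(3):
                w = u[offset : offset + nv].reshape(g.grid_shape)
                out = out + (np.roll(w, 1, axis=a) - w)
                offset += nv
            return out.ravel()

        k_op = scipy.sparse.linalg.LinearOperator(
            (g.n_data + 3 * nv, nv), matvec=matvec, rmatvec=rmatvec
        )
        smax = scipy.sparse.linalg.svds(k_op, k=1, return_singular_vectors=False)[0]
        # the spectral gap of K^T K is small on this geometry, so the power
        # method needs a few hundred multiplications to settle below 0.1%
        gamma = power_method_norm(g, n_iters=150, seed=3)
        assert abs(gamma - smax) / smax < 1e-3
        gamma2 = power_method_norm(g, n_iters=2, seed=3)
        assert gamma2 <= smax * (1 + 1e-9)  # Rayleigh quotient is a lower bound

    def test_zero_iterations_rejected(self, small_geom):
        with pytest.raises(ValueError):
            power_method_norm(small_geom, n_iters=0)


class TestCPProx:
    def test_ball_prox_inside_maps_to_zero(self):
        y = np.zeros(4)
        term = np.array([0.1, 0.0, 0.0, 0.0])
        out = cp_dual_ball_prox(y, term, sigma=1.0, epsilon=5.0)
        np.testing.assert_allclose(out, 0.0)

    def test_ball_prox_epsilon_zero_is_identity(self, rng):
        y = rng.standard_normal(6)
        term = rng.standard_normal(6)
        out = cp_dual_ball_prox(y, term, sigma=0.7, epsilon=0.0)
        np.testing.assert_allclose(out, y + 0.7 * term, atol=1e-15)

    def test_ball_prox_radial_shrinkage(self):
        ybar = np.array([3.0, 4.0])  # norm 5, sigma*eps = 2
        out = cp_dual_ball_prox(ybar, np.zeros(2), sigma=1.0, epsilon=2.0)
        assert np.linalg.norm(out) == pytest.approx(3.0)
        np.testing.assert_allclose(out / np.linalg.norm(out), ybar / 5.0)

    def test_gradient_prox_identity_below_lambda(self, rng):
        w = 1e-3 * rng.standard_normal((3, 4, 4, 2))
        out = cp_dual_gradient_prox(w, np.zeros((4, 4, 2)), sigma=1.0, lambda_=1.0)
        np.testing.assert_allclose(out, w, atol=1e-15)

    def test_gradient_prox_scales_to_lambda_ball(self):
        w = np.zeros((3, 1, 1, 1))
        w[0, 0, 0, 0], w[1, 0, 0, 0] = 3.0, 4.0
        out = cp_dual_gradient_prox(w, np.zeros((1, 1, 1)), sigma=1.0, lambda_=1.0)
        np.testing.assert_allclose(out[:, 0, 0, 0], [0.6, 0.8, 0.0], atol=1e-15)

    def test_gradient_prox_dual_norm_never_exceeds_lambda(self, rng):
        lam = 0.4
        w = rng.standard_normal((3, 5, 4, 3))
        xb = rng.standard_normal((5, 4, 3))
        out = cp_dual_gradient_prox(w, xb, sigma=2.0, lambda_=lam)
        mags = np.sqrt(np.sum(out**2, axis=0))
        assert mags.max() <= lam + 1e-12

    def test_gradient_prox_lambda_zero_rejected(self):
        with pytest.raises(ValueError):
            cp_dual_gradient_prox(np.zeros((3, 2, 2, 2)), np.zeros((2, 2, 2)), 1.0, 0.0)


class TestCPSolve:
    def test_first_iteration_state(self, textured_fixture, small_geom):
        _, b, nn = textured_fixture
        cfg = SolverConfig(
            lambda_=0.005, max_iter=1, tol=0.0, cp=CPOptions(epsilon=nn, power_iters=10)
        )
        vol, trace = cp_solve(b, small_geom, cfg)
        state = trace.state
        sigma = 1.0 / state.gamma_norm
        expected_y = cp_dual_ball_prox(np.zeros_like(b.values), -b.values, sigma, nn)
        np.testing.assert_allclose(state.y, expected_y, atol=1e-14)
        # theta = 1 extrapolation from x0 = 0: x_bar = 2 x1 - x0
        np.testing.assert_allclose(state.x_bar, 2.0 * state.x, atol=1e-14)
        assert state.x.min() >= 0.0

    def test_iterates_nonnegative_and_dual_feasible(self, textured_fixture, small_geom):
        _, b, nn = textured_fixture
        lam = 0.005
        cfg = SolverConfig(
            lambda_=lam, max_iter=50, tol=0.0, cp=CPOptions(epsilon=nn, power_iters=10)
        )
        vol, trace = cp_solve(b, small_geom, cfg)
        assert vol.values.min() >= 0.0
        mags = np.sqrt(np.sum(trace.state.w**2, axis=0))
        assert mags.max() <= lam + 1e-12


class TestConfigValidation:
    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(lambda_=-0.1)
        with pytest.raises(ValueError):
            SolverConfig(lambda_="sometimes")
        from dbtrecon.solvers import SGPOptions

        with pytest.raises(ValueError):
            SGPOptions(sigma=1.5)
        with pytest.raises(ValueError):
            CPOptions(theta=2.0)
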