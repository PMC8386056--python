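import numpy as np
import pytest

from fuseprio.fusion import (
    fit,
    grad_u,
    objective_elementwise,
    objective_traceform,
    update_u,
    update_w,
)


def _instance(rng, n=5, k=4, r=3):
    X = rng.standard_normal((n, k))
    U = rng.standard_normal((k, r))
    A = rng.standard_normal((n, r))
    S = rng.random((n, n))
    W = rng.random((n, n))
    W = (W + W.T) / 2
    return X, U, A, S, W


def _objective_loops(U, W, S, X, A, lam):
    """Independent scalar triple-loop oracle for the pair-sum objective."""
    n = X.shape[0]
    P = X @ U
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += S[i, j] * np.sum((P[i] - A[j]) ** 2)
            total += W[i, j] * np.sum((P[i] - P[j]) ** 2)
            total += lam * (np.sqrt(W[i, j]) - 1.0) ** 2
    return 0.5 * total


class TestObjective:
    def test_matches_loop_oracle(self, rng):
        X, U, A, S, W = _instance(rng)
        expected = _objective_loops(U, W, S, X, A, lam=1.3)
        assert objective_elementwise(U, W, S, X, A, 1.3) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_when_all_terms_vanish(self, rng):
        # identical projected rows, unit weights, zero affinity
        n, k, r = 4, 3, 2
        X = np.tile(rng.standard_normal(k), (n, 1))
        U = rng.standard_normal((k, r))
        W = np.ones((n, n))
        S = np.zeros((n, n))
        A = rng.standard_normal((n, r))
        assert objective_elementwise(U, W, S, X, A, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_penalty_only_closed_form(self, rng):
        n = 6
        X = rng.standard_normal((n, 3))
        U = rng.standard_normal((3, 2))
        A = rng.standard_normal((n, 2))
        lam = 0.7
        val = objective_elementwise(U, np.zeros((n, n)), np.zeros((n, n)), X, A, lam)
        assert val == pytest.approx(0.5 * n * n * lam, abs=1e-10)

    def test_nonpositive_lam_errors(self, rng):
        X, U, A, S, W = _instance(rng)
        with pytest.raises(ValueError):
            objective_elementwise(U, W, S, X, A, 0.0)


class TestTraceform:
    def test_equals_elementwise_on_random_instances(self, rng):
        for _ in range(10):
            X, U, A, S, W = _instance(rng, n=6, k=5, r=3)
            a = objective_elementwise(U, W, S, X, A, 0.9)
            b = objective_traceform(U, W, S, X, A, 0.9)
            assert b == pytest.approx(a, rel=1e-8)

    def test_w_term_is_twice_the_laplacian_trace(self, rng):
        # oracle fixes the Laplacian-identity constant at 2
        X, U, A, S, W = _instance(rng)
        P = X @ U
        loops = sum(
            W[i, j] * np.sum((P[i] - P[j]) ** 2)
            for i in range(5)
            for j in range(5)
        )
        L = np.diag(W.sum(axis=1)) - W
        assert loops == pytest.approx(2.0 * np.trace(U.T @ X.T @ L @ X @ U), rel=1e-10)

    def test_zero_affinity_drops_s_terms(self, rng):
        X, U, A, _, W = _instance(rng)
        S0 = np.zeros((5, 5))
        a = objective_traceform(U, W, S0, X, A, 1.0)
        pen = 0.5 * 1.0 * ((np.sqrt(W) - 1) ** 2).sum()
        P = X @ U
        wterm = 0.5 * sum(
            W[i, j] * np.sum((P[i] - P[j]) ** 2) for i in range(5) for j in range(5)
        )
        assert a == pytest.approx(wterm + pen, rel=1e-10)


class TestUpdateW:
    def test_zero_distance_gives_unit_weight(self, rng):
        X = np.vstack([np.ones(3), np.ones(3), rng.standard_normal(3)])
        U = rng.standard_normal((3, 2))
        net = update_w(U, X, lam=1.0)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_unit_case_equals_grid_minimum(self):
        # lam=1, d^2=1: closed form gives 0.25; brute-force grid confirms
        grid = np.linspace(0, 1, 100001)
        vals = grid * 1.0 + (np.sqrt(grid) - 1.0) ** 2
        assert grid[np.argmin(vals)] == pytest.approx(0.25, abs=1e-4)
        assert (1.0 / (1.0 + 1.0)) ** 2 == pytest.approx(0.25)

    def test_monotone_in_lam(self, rng):
        X = rng.standard_normal((4, 3))
        U = rng.standard_normal((3, 2))
        prev = None
        for lam in (0.1, 1.0, 10.0, 1e4, 1e8):
            w = update_w(U, X, lam=lam).weights
            off = w[np.triu_indices(4, 1)]
            if prev is not None:
                assert np.all(off >= prev - 1e-15)
            prev = off
        assert np.all(off >= 0.999)

    def test_symmetric_unit_interval_zero_diagonal(self, rng):
        X = rng.standard_normal((6, 4))
        U = rng.standard_normal((4, 3))
        w = update_w(U, X, lam=0.5).weights
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        assert w.min() >= 0 and w.max() <= 1
        np.testing.assert_array_equal(np.diag(w), 0.0)

    def test_beats_dense_grid_on_random_pairs(self, rng):
        # per-pair global optimality of the closed form (grid oracle)
        d2 = rng.random(1000) * 10
        lam = rng.random(1000) * 5 + 1e-3
        w_star = (lam / (d2 + lam)) ** 2
        grid = np.linspace(0.0, 1.0, 10_001)
        f = lambda w, d2_, lam_: w * d2_ + lam_ * (np.sqrt(w) - 1.0) ** 2
        best_grid = np.min(f(grid[None, :], d2[:, None], lam[:, None]), axis=1)
        assert np.all(f(w_star, d2, lam) <= best_grid + 1e-12)


class TestGradU:
    def _fd(self, U, W, S, X, A, lam, h=1e-5):
        g = np.zeros_like(U)
        for i in range(U.shape[0]):
            for j in range(U.shape[1]):
                up = U.copy(); up[i, j] += h
                dn = U.copy(); dn[i, j] -= h
                g[i, j] = (
                    objective_elementwise(up, W, S, X, A, lam)
                    - objective_elementwise(dn, W, S, X, A, lam)
                ) / (2 * h)
        return g

    def test_matches_central_differences(self, rng):
        X, U, A, S, W = _instance(rng, n=8, k=4, r=3)
        g = grad_u(U, W, S, X, A)
        fd = self._fd(U, W, S, X, A, lam=1.0)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5

    def test_zero_at_constant_objective(self, rng):
        X, U, A, _, _ = _instance(rng)
        Z = np.zeros((5, 5))
        np.testing.assert_array_equal(grad_u(U, Z, Z, X, A), 0.0)

    def test_near_zero_at_stationary_point(self, rng):
        # the gradient is linear in U, so the stationary point solves
        # (X' D_r X + 2 X' L_W X) U = X' S A exactly
        X, U, A, S, W = _instance(rng, n=6, k=3, r=2)
        d_row = S.sum(axis=1)
        L = np.diag(W.sum(axis=1)) - W
        M = X.T @ (d_row[:, None] * X) + 2.0 * X.T @ L @ X
        U_star = np.linalg.solve(M, X.T @ S @ A)
        scale = np.linalg.norm(grad_u(np.zeros_like(U), W, S, X, A)) + 1.0
        assert np.linalg.norm(grad_u(U_star, W, S, X, A)) < 1e-6 * scale


class TestUpdateU:
    def test_zero_gradient_is_noop(self, rng):
        U = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(update_u(U, np.zeros_like(U), 0.1), U)

    def test_converges_on_quadratic_toy(self, rng):
        # f(U) = ||U - B||^2 has analytic minimizer B
        B = rng.standard_normal((3, 2))
        U = np.zeros((3, 2))
        for _ in range(500):
            U = update_u(U, 2 * (U - B), step=0.1)
        np.testing.assert_allclose(U, B, atol=1e-6)

    def test_nonpositive_step_errors(self, rng):
        U = rng.standard_normal((2, 2))
        with pytest.raises(ValueError):
            update_u(U, U, 0.0)


class TestFit:
    def _random_inputs(self, rng, n=30, k=6, r=4):
        X = rng.standard_normal((n, k))
        S = rng.random((n, n)) * 0.5
        A = rng.standard_normal((n, r))
        return X, S, A

    def test_trace_monotone_non_increasing(self, rng):
        for seed in range(3):
            r2 = np.random.default_rng(seed)
            X, S, A = self._random_inputs(r2)
            model = fit(X, S, A, lam=1.0, max_iter=60)
            tr = np.array(model.objective_trace)
            assert np.all(np.diff(tr) <= 1e-9 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_huge_lam_saturates_weights(self, rng):
        X, S, A = self._random_inputs(rng, n=15)
        model = fit(X, S, A, lam=1e9, max_iter=30)
        off = model.network.weights[np.triu_indices(15, 1)]
        assert np.all(off >= 0.999)

    def test_identical_target_rows_get_unit_weight(self, rng):
        X, S, A = self._random_inputs(rng, n=10)
        X[1] = X[0]
        model = fit(X, S, A, lam=1.0, max_iter=30)
        assert model.network.weights[0, 1] == pytest.approx(1.0)

    def test_weights_in_unit_interval_and_symmetric(self, rng):
        X, S, A = self._random_inputs(rng)
        model = fit(X, S, A, lam=0.5, max_iter=40)
        w = model.network.weights
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        assert w.min() >= 0 and w.max() <= 1

    def test_converges_and_reports_iterations(self, rng):
        X, S, A = self._random_inputs(rng, n=20)
        model = fit(X, S, A, lam=1.0, max_iter=200, tol=1e-5)
        assert model.converged
        assert model.n_iter < 200
        assert len(model.objective_trace) == model.n_iter + 1
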