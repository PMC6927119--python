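import numpy as np
import pytest

from knmbp.propagation import (
    PropagationParams,
    adagrad_solve,
    gradient,
    linear_solve,
    normalized_laplacian,
    objective,
    pairwise_smoothness,
)


def kron_oracle(y, lap_m, lap_d, lambda_m, lambda_d):
    """Dense Kronecker-product solve of (2I + lm*Lm) F + ld*F*Ld = 2Y."""
    nm, nd = y.shape
    a = np.kron(np.eye(nd), 2.0 * np.eye(nm) + lambda_m * lap_m)
    a += np.kron(lambda_d * lap_d.T, np.eye(nm))
    return np.linalg.solve(a, 2.0 * y.ravel(order="F")).reshape((nm, nd), order="F")


def random_laplacian(rng, n):
    s = rng.random((n, n))
    s = (s + s.T) / 2
    return normalized_laplacian(s), s


class TestNormalizedLaplacian:
    def test_identity_similarity_gives_zero(self):
        np.testing.assert_allclose(normalized_laplacian(np.eye(4)), 0.0, atol=1e-12)

    def test_complete_graph_eigenvalues(self):
        lap = normalized_laplacian(np.ones((3, 3)))
        np.testing.assert_allclose(lap, np.eye(3) - np.ones((3, 3)) / 3, atol=1e-12)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(lap)), [0, 1, 1], atol=1e-9)

    def test_sqrt_degree_vector_in_null_space(self, rng):
        lap, s = random_laplacian(rng, 6)
        null = np.sqrt(s.sum(axis=1))
        assert np.abs(lap @ null).max() < 1e-9

    def test_psd_with_spectrum_below_two(self, rng):
        lap, _ = random_laplacian(rng, 8)
        eig = np.linalg.eigvalsh(lap)
        assert eig.min() >= -1e-8
        assert eig.max() <= 2 + 1e-8

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            normalized_laplacian(rng.random((4, 4)))

    def test_zero_degree_rows_guarded(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 1.0
        lap = normalized_laplacian(s)
        assert np.isfinite(lap).all()


class TestTraceIdentity:
    @pytest.mark.parametrize("seed", range(3))
    def test_pairwise_sum_equals_trace_form_rows(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random((5, 5))
        s = (s + s.T) / 2
        f = rng.random((5, 4))
        lap = normalized_laplacian(s)
        assert pairwise_smoothness(f, s) == pytest.approx(
            float(np.trace(f.T @ lap @ f)), abs=1e-8
        )

    def test_pairwise_sum_equals_trace_form_columns(self, rng):
        s = rng.random((4, 4))
        s = (s + s.T) / 2
        f = rng.random((5, 4))
        lap = normalized_laplacian(s)
        assert pairwise_smoothness(f.T, s) == pytest.approx(
            float(np.trace(f @ lap @ f.T)), abs=1e-8
        )


class TestObjectiveAndGradient:
    def test_zero_at_y_without_regularization(self, rng):
        lap_m, _ = random_laplacian(rng, 4)
        lap_d, _ = random_laplacian(rng, 3)
        y = rng.random((4, 3))
        params = PropagationParams(lambda_m=0.0, lambda_d=0.0)
        assert objective(y, y, lap_m, lap_d, params) == 0.0
        np.testing.assert_array_equal(gradient(y, y, lap_m, lap_d, params), 0.0)

    def test_regularized_objective_at_y_is_nonnegative_psd_form(self, rng):
        lap_m, _ = random_laplacian(rng, 4)
        lap_d, _ = random_laplacian(rng, 3)
        y = (rng.random((4, 3)) < 0.4).astype(float)
        params = PropagationParams(lambda_m=2.0, lambda_d=1.0)
        assert objective(y, y, lap_m, lap_d, params) >= 0.0

    def test_hand_expansion_on_2x2(self):
        # fully written-out arithmetic, independent of the matrix expressions
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        f = np.array([[0.5, 0.25], [0.75, 1.0]])
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        lap = normalized_laplacian(s)
        params = PropagationParams(lambda_m=2.0, lambda_d=4.0)
        expected = sum(
            (f[i, j] - y[i, j]) ** 2 for i in range(2) for j in range(2)
        )
        expected += 1.0 * sum(
            f[i, k] * lap[i, j] * f[j, k]
            for i in range(2) for j in range(2) for k in range(2)
        )
        expected += 2.0 * sum(
            f[k, i] * lap[i, j] * f[k, j]
            for i in range(2) for j in range(2) for k in range(2)
        )
        assert objective(f, y, lap, lap, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        nm, nd = 4, 3
        lap_m, _ = random_laplacian(rng, nm)
        lap_d, _ = random_laplacian(rng, nd)
        y = rng.random((nm, nd))
        f = rng.random((nm, nd))
        params = PropagationParams(lambda_m=1.5, lambda_d=0.7)
        g = gradient(f, y, lap_m, lap_d, params)
        h = 1e-6
        fd = np.zeros_like(f)
        for i in range(nm):
            for j in range(nd):
                e = np.zeros_like(f)
                e[i, j] = h
                fd[i, j] = (
                    objective(f + e, y, lap_m, lap_d, params)
                    - objective(f - e, y, lap_m, lap_d, params)
                ) / (2 * h)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5

    def test_gradient_is_affine_in_f(self, rng):
        lap_m, _ = random_laplacian(rng, 4)
        lap_d, _ = random_laplacian(rng, 3)
        y = rng.random((4, 3))
        params = PropagationParams(lambda_m=1.0, lambda_d=2.0)
        f1, f2 = rng.random((4, 3)), rng.random((4, 3))
        lhs = (
            gradient(f1, y, lap_m, lap_d, params)
            + gradient(f2, y, lap_m, lap_d, params)
            - gradient(np.zeros_like(f1), y, lap_m, lap_d, params)
        )
        np.testing.assert_allclose(
            lhs, gradient(f1 + f2, y, lap_m, lap_d, params), atol=1e-10
        )


class TestSolvers:
    def test_unregularized_solution_is_y(self, rng):
        lap_m, _ = random_laplacian(rng, 5)
        lap_d, _ = random_laplacian(rng, 4)
        y = (rng.random((5, 4)) < 0.4).astype(float)
        params = PropagationParams(lambda_m=0.0, lambda_d=0.0, tol=1e-14, max_iter=20000)
        np.testing.assert_allclose(adagrad_solve(y, lap_m, lap_d, params), y, atol=1e-4)
        np.testing.assert_allclose(linear_solve(y, lap_m, lap_d, params), y, atol=1e-10)

    def test_adagrad_matches_kron_oracle_4x3(self, rng):
        lap_m, _ = random_laplacian(rng, 4)
        lap_d, _ = random_laplacian(rng, 3)
        y = (rng.random((4, 3)) < 0.5).astype(float)
        params = PropagationParams(
            lambda_m=1.0, lambda_d=1.0, eta0=0.5, tol=1e-15, max_iter=50000
        )
        f = adagrad_solve(y, lap_m, lap_d, params)
        np.testing.assert_allclose(f, kron_oracle(y, lap_m, lap_d, 1.0, 1.0), atol=1e-4)

    def test_linear_solver_matches_kron_oracle(self, rng):
        lap_m, _ = random_laplacian(rng, 6)
        lap_d, _ = random_laplacian(rng, 5)
        y = rng.random((6, 5))
        for lam in (0.25, 1.0, 4.0):
            params = PropagationParams(lambda_m=lam, lambda_d=lam)
            np.testing.assert_allclose(
                linear_solve(y, lap_m, lap_d, params),
                kron_oracle(y, lap_m, lap_d, lam, lam),
                atol=1e-10,
            )

    def test_approximate_stationarity_at_convergence(self, rng):
        lap_m, _ = random_laplacian(rng, 5)
        lap_d, _ = random_laplacian(rng, 4)
        y = (rng.random((5, 4)) < 0.4).astype(float)
        params = PropagationParams(
            lambda_m=2.0, lambda_d=2.0, eta0=0.5, tol=1e-15, max_iter=50000
        )
        f = adagrad_solve(y, lap_m, lap_d, params)
        g0 = np.linalg.norm(gradient(y, y, lap_m, lap_d, params))
        g = np.linalg.norm(gradient(f, y, lap_m, lap_d, params))
        assert g / g0 < 1e-3

    def test_objective_nonincreasing_after_burn_in(self, rng):
        lap_m, _ = random_laplacian(rng, 5)
        lap_d, _ = random_laplacian(rng, 4)
        y = (rng.random((5, 4)) < 0.4).astype(float)
        params = PropagationParams(lambda_m=1.0, lambda_d=1.0, tol=1e-12, max_iter=2000)
        _, history = adagrad_solve(y, lap_m, lap_d, params, return_history=True)
        tail = np.array(history[5:])
        assert (np.diff(tail) <= 1e-10).all()

    def test_monotone_shrinkage_in_lambda(self, rng):
        lap_m, s_m = random_laplacian(rng, 5)
        lap_d, _ = random_laplacian(rng, 4)
        y = (rng.random((5, 4)) < 0.4).astype(float)
        traces = []
        for lam in (0.0, 0.5, 1.0, 2.0, 4.0):
            params = PropagationParams(lambda_m=lam, lambda_d=0.0)
            f = linear_solve(y, lap_m, lap_d, params)
            traces.append(float(np.trace(f.T @ lap_m @ f)))
        assert all(a >= b - 1e-10 for a, b in zip(traces, traces[1:]))
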