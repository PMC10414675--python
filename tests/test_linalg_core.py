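"""Unit and property tests for the numerical kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mixgrn.linalg_core import (
    GlassoConvergenceError,
    HyperParams,
    l21_norm,
    negative_log_likelihood,
    penalized_objective,
    row_weight_matrix,
    solve_precision_glasso,
    solve_precision_riccati,
    solve_sylvester_kron,
    solve_sylvester_svd,
    spd_principal_sqrt,
)

from conftest import random_psd, random_spd


class TestL21Norm:
    def test_pythagorean_row(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == pytest.approx(5.0)

    def test_identity(self):
        assert l21_norm(np.eye(2)) == pytest.approx(2.0)

    def test_matches_naive_loop(self, rng):
        M = rng.standard_normal((4, 3))
        naive = sum(
            np.sqrt(sum(M[i, j] ** 2 for j in range(3))) for i in range(4)
        )
        assert l21_norm(M) == pytest.approx(naive, rel=1e-12)

    @given(
        arrays(
            float,
            (3, 4),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_nonnegative_and_scales(self, M):
        v = l21_norm(M)
        assert v >= 0
        assert l21_norm(2.0 * M) == pytest.approx(2.0 * v, rel=1e-9, abs=1e-9)


class TestRowWeights:
    def test_zero_row_smoothed(self):
        w = row_weight_matrix(np.zeros((1, 3)), zeta=1e-8)
        assert w[0] == pytest.approx(1.0 / (2e-4))

    def test_limit_of_nonzero_row(self):
        w = row_weight_matrix(np.array([[3.0, 4.0]]), zeta=1e-16)
        assert w[0] == pytest.approx(0.1, rel=1e-6)

    def test_gradient_of_l21_as_zeta_vanishes(self, rng):
        # 2 * diag(w) * M approaches the L2,1 subgradient on nonzero rows
        M = rng.standard_normal((5, 4)) + 0.5
        eps = 1e-7
        for zeta in (1e-8, 1e-12):
            G = 2.0 * row_weight_matrix(M, zeta)[:, None] * M
            i, j = 2, 1
            Mp = M.copy()
            Mp[i, j] += eps
            fd = (l21_norm(Mp) - l21_norm(M)) / eps
            assert G[i, j] == pytest.approx(fd, rel=1e-4)

    def test_rejects_nonpositive_zeta(self):
        with pytest.raises(ValueError):
            row_weight_matrix(np.eye(2), zeta=0.0)


class TestSylvesterSolvers:
    def test_kron_mu_zero_square_invertible(self, rng):
        X = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        Y = rng.standard_normal((4, 3))
        B = solve_sylvester_kron(X, Y, np.eye(3), 0.0)
        np.testing.assert_allclose(B, np.linalg.solve(X, Y), atol=1e-10)

    def test_identity_design_scalar_shrinkage(self):
        # X = I, K = I: every entry solves (1 + mu) b = y
        Y = np.arange(12.0).reshape(4, 3)
        B = solve_sylvester_kron(np.eye(4), Y, np.eye(3), 2.5)
        np.testing.assert_allclose(B, Y / 3.5, atol=1e-12)

    def test_kron_residual_random_instance(self, rng):
        X = rng.standard_normal((6, 4))
        Y = rng.standard_normal((6, 5))
        K = random_spd(rng, 5)
        B = solve_sylvester_kron(X, Y, K, 0.7)
        res = X.T @ X @ B + 0.7 * B @ K - X.T @ Y
        assert np.linalg.norm(res) < 1e-9

    def test_svd_mu_zero_is_min_norm_lsq(self, rng):
        X = rng.standard_normal((5, 9))  # underdetermined
        Y = rng.standard_normal((5, 4))
        B = solve_sylvester_svd(X, Y, np.ones(4), np.eye(4), 0.0)
        np.testing.assert_allclose(B, np.linalg.pinv(X) @ Y, atol=1e-9)

    def test_svd_identity_weights_is_ridge(self, rng):
        # C = I, Omega0 = I collapses to the ridge-type closed form
        X = rng.standard_normal((10, 6))
        Y = rng.standard_normal((10, 4))
        mu = 1.3
        B = solve_sylvester_svd(X, Y, np.ones(4), np.eye(4), mu)
        ridge = np.linalg.solve(X.T @ X + mu * np.eye(6), X.T @ Y)
        np.testing.assert_allclose(B, ridge, atol=1e-9)

    @pytest.mark.parametrize("mu", [0.0, 0.1, 1.0, 10.0])
    def test_svd_agrees_with_kron_oracle(self, rng, mu):
        n, p, s = 8, 12, 6
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, s))
        c = rng.uniform(0.5, 2.0, s)
        Om = random_spd(rng, s)
        B_svd = solve_sylvester_svd(X, Y, c, Om, mu)
        if mu == 0:
            np.testing.assert_allclose(B_svd, np.linalg.pinv(X) @ Y, atol=1e-8)
            return
        K = np.diag(c) @ np.linalg.inv(Om)
        B_kron = solve_sylvester_kron(X, Y, K, mu)
        assert (
            np.linalg.norm(B_svd - B_kron) / np.linalg.norm(B_kron) < 1e-7
        )

    def test_svd_solution_in_row_space(self, rng):
        # rank-deficient X: component outside span(V1) must vanish
        X = rng.standard_normal((4, 8))
        Y = rng.standard_normal((4, 3))
        B = solve_sylvester_svd(X, Y, np.ones(3), np.eye(3), 0.5)
        _, _, Vt = np.linalg.svd(X)
        null = Vt[4:]  # basis of the null space of X
        assert np.abs(null @ B).max() < 1e-10

    def test_svd_rejects_bad_inputs(self, rng):
        X = rng.standard_normal((5, 3))
        Y = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            solve_sylvester_svd(X, Y, np.ones(2), np.eye(2), -1.0)
        with pytest.raises(ValueError):
            solve_sylvester_svd(X, Y, np.ones(2), -np.eye(2), 1.0)


class TestSpdSqrt:
    def test_scaled_identity(self):
        np.testing.assert_allclose(spd_principal_sqrt(4 * np.eye(3)), 2 * np.eye(3))

    def test_diagonal(self):
        np.testing.assert_allclose(
            spd_principal_sqrt(np.diag([9.0, 16.0])), np.diag([3.0, 4.0])
        )

    def test_defining_property_random_spd(self, rng):
        M = random_spd(rng, 6)
        R = spd_principal_sqrt(M)
        np.testing.assert_allclose(R @ R, M, atol=1e-9)
        np.testing.assert_allclose(R, R.T, atol=1e-12)

    def test_rejects_asymmetric(self, rng):
        with pytest.raises(ValueError):
            spd_principal_sqrt(rng.standard_normal((4, 4)))


class TestRiccati:
    def test_identity_scalar_root(self):
        Om = solve_precision_riccati(np.eye(4), 1.0)
        np.testing.assert_allclose(Om, 0.5 * np.eye(4), atol=1e-12)

    def test_identity_quarter_lambda(self):
        # scalar root (-1 + sqrt(1 + 8*0.25)) / (4*0.25) = sqrt(3) - 1
        Om = solve_precision_riccati(np.eye(3), 0.25)
        np.testing.assert_allclose(Om, (np.sqrt(3) - 1) * np.eye(3), atol=1e-12)

    def test_plugback_and_spd_random_psd(self, rng):
        P = random_psd(rng, 6)
        lam = 0.3
        Om = solve_precision_riccati(P, lam)
        res = 2 * lam * Om @ Om + P @ Om - np.eye(6)
        assert np.linalg.norm(res) < 1e-9
        assert np.linalg.eigvalsh(Om)[0] > 0

    def test_sqrt_factor_commutes_with_p(self, rng):
        P = random_psd(rng, 5)
        lam = 0.7
        R = spd_principal_sqrt(P @ P + 8 * lam * np.eye(5))
        assert np.linalg.norm(R @ P - P @ R) < 1e-8

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            solve_precision_riccati(np.eye(2), 0.0)


class TestGlasso:
    def test_lambda_zero_is_inverse(self, rng):
        P = random_spd(rng, 4)
        np.testing.assert_allclose(
            solve_precision_glasso(P, 0.0), np.linalg.inv(P), atol=1e-8
        )

    def test_full_shrinkage_gives_diagonal(self, rng):
        P = random_spd(rng, 4)
        lam = np.abs(P - np.diag(np.diag(P))).max() + 0.01
        Om = solve_precision_glasso(P, lam)
        np.testing.assert_allclose(Om, np.diag(1.0 / np.diag(P)), atol=1e-6)

    def test_two_by_two_soft_threshold(self):
        # analytic 2x2 solution: covariance off-diagonal soft-thresholded
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        Om = solve_precision_glasso(P, 0.2)
        W = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(Om, np.linalg.inv(W), atol=1e-6)

    def test_singular_p_with_zero_lambda_fails(self):
        with pytest.raises((np.linalg.LinAlgError, GlassoConvergenceError)):
            solve_precision_glasso(np.ones((3, 3)), 0.0)


class TestObjectives:
    def test_exact_fit_identity_omega_is_zero(self, rng):
        X = rng.standard_normal((6, 3))
        B = rng.standard_normal((3, 4))
        assert negative_log_likelihood(B, np.eye(4), X, X @ B) == pytest.approx(0.0)

    def test_exact_fit_scaled_omega(self, rng):
        X = rng.standard_normal((6, 3))
        B = rng.standard_normal((3, 4))
        c = 2.7
        val = negative_log_likelihood(B, c * np.eye(4), X, X @ B)
        assert val == pytest.approx(-4 * np.log(c), rel=1e-10)

    def test_nll_matches_naive(self, rng):
        X = rng.standard_normal((7, 3))
        Y = rng.standard_normal((7, 4))
        B = rng.standard_normal((3, 4))
        Om = random_spd(rng, 4)
        R = Y - X @ B
        P = R.T @ R / 7
        naive = np.trace(P @ Om) - np.log(np.linalg.det(Om))
        assert negative_log_likelihood(B, Om, X, Y) == pytest.approx(
            naive, rel=1e-10
        )

    def test_zero_penalties_equal_nll(self, rng):
        X = rng.standard_normal((6, 3))
        Y = rng.standard_normal((6, 4))
        B = rng.standard_normal((3, 4))
        Om = random_spd(rng, 4)
        hp = HyperParams(0.0, 0.0)
        for variant in ("l1", "l2"):
            assert penalized_objective(B, Om, X, Y, hp, variant) == pytest.approx(
                negative_log_likelihood(B, Om, X, Y), rel=1e-12
            )

    def test_zero_b_identity_omega(self, rng):
        X = rng.standard_normal((5, 3))
        Y = rng.standard_normal((5, 4))
        hp = HyperParams(0.4, 0.0)
        val = penalized_objective(np.zeros((3, 4)), np.eye(4), X, Y, hp, "l1")
        assert val == pytest.approx(np.trace(Y.T @ Y) / 5 + 0.4 * 0.0, rel=1e-10)

    def test_matches_naive_formula_both_variants(self, rng):
        X = rng.standard_normal((6, 3))
        Y = rng.standard_normal((6, 4))
        B = rng.standard_normal((3, 4))
        Om = random_spd(rng, 4)
        hp = HyperParams(0.3, 0.7)
        nll = negative_log_likelihood(B, Om, X, Y)
        pen_b = sum(np.linalg.norm(B[:, j]) for j in range(4))
        off = sum(
            abs(Om[i, j]) for i in range(4) for j in range(4) if i != j
        )
        assert penalized_objective(B, Om, X, Y, hp, "l1") == pytest.approx(
            nll + 0.3 * off + 0.7 * pen_b, rel=1e-10
        )
        assert penalized_objective(B, Om, X, Y, hp, "l2") == pytest.approx(
            nll + 0.3 * np.sum(Om**2) + 0.7 * pen_b, rel=1e-10
        )

    def test_permutation_invariance(self, rng):
        # simultaneous gene permutation leaves the objective unchanged
        X = rng.standard_normal((6, 3))
        Y = rng.standard_normal((6, 5))
        B = rng.standard_normal((3, 5))
        Om = random_spd(rng, 5)
        hp = HyperParams(0.3, 0.7)
        perm = rng.permutation(5)
        for variant in ("l1", "l2"):
            v1 = penalized_objective(B, Om, X, Y, hp, variant)
            v2 = penalized_objective(
                B[:, perm], Om[np.ix_(perm, perm)], X, Y[:, perm], hp, variant
            )
            assert v1 == pytest.approx(v2, rel=1e-10)

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            penalized_objective(
                np.zeros((2, 2)), np.eye(2), np.eye(2), np.eye(2),
                HyperParams(0.1, 0.1), "huber",
            )


def test_smoothed_penalty_converges_to_l21(rng):
    """The zeta-smoothed group penalty approaches the exact L2,1 value."""
    B = rng.standard_normal((5, 4)) + 1.0  # no zero columns
    exact = l21_norm(B.T)
    for zeta in (1e-4, 1e-8, 1e-12):
        smoothed = float(np.sum(np.sqrt(np.sum(B * B, axis=0) + zeta)))
        assert abs(smoothed - exact) <= 4 * np.sqrt(zeta)
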