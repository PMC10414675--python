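"""Numerical kernels for mixed-norm regularized multivariate regression.

This module contains the building blocks shared by all four estimator
variants:

* the :math:`L_{2,1}` matrix norm (sum of row-wise Euclidean norms) and its
  smoothed reweighting matrix used by the IRLS coefficient updates,
* solvers for the inhomogeneous Sylvester equation
  :math:`X^TXB + \\mu\\,B\\,C\\Omega_0^{-1} = X^TY` that defines the
  coefficient update (a dense Kronecker-product oracle for small problems
  and the SVD change-of-variables route that scales to genomic dimensions),
* the closed-form solution of the quadratic matrix (algebraic Riccati)
  equation :math:`2\\lambda_1\\Omega^2 + P\\Omega - I = 0` arising from the
  Frobenius-penalized precision update, via the SPD principal square root,
* a graphical-lasso precision solver with an explicit KKT certificate,
* the Gaussian negative log-likelihood and the two penalized objectives.

All tolerances are module constants; nothing here touches files.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy import linalg as sla
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

#: singular values below this fraction of the largest are treated as zero
SVD_RTOL = 1e-12
#: asymmetry tolerance for matrices that must be symmetric
SYM_TOL = 1e-8
#: default smoothing constant for the L2,1 reweighting
DEFAULT_ZETA = 1e-8
#: KKT slack allowed for the graphical-lasso certificate
GLASSO_KKT_TOL = 1e-6


@dataclass(frozen=True)
class HyperParams:
    """Regularization strengths: ``lambda1`` on Ω, ``lambda2`` on B."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("hyperparameters must be non-negative")


def l21_norm(M: np.ndarray) -> float:
    """Sum of the Euclidean norms of the rows of ``M``.

    For a coefficient matrix this is the group-sparsity penalty that drives
    whole rows toward zero (joint selection of a predictor across all
    responses).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("l21_norm expects a 2-D array")
    return float(np.sum(np.sqrt(np.sum(M * M, axis=1))))


def row_weight_matrix(M: np.ndarray, zeta: float = DEFAULT_ZETA) -> np.ndarray:
    """Diagonal of the smoothed IRLS weight matrix for ``M``.

    Entry ``i`` is ``1 / (2 * sqrt(||m_i||^2 + zeta))`` where ``m_i`` is the
    i-th row; ``zeta > 0`` keeps the weights finite on zero rows. Returned as
    a 1-D vector holding the diagonal (the matrix is diagonal by
    construction).
    """
    if zeta <= 0:
        raise ValueError("zeta must be strictly positive")
    M = np.asarray(M, dtype=float)
    sq = np.sum(M * M, axis=1)
    return 1.0 / (2.0 * np.sqrt(sq + zeta))


def _as_diag_vector(C: np.ndarray, name: str = "C") -> np.ndarray:
    """Accept a diagonal matrix or its diagonal vector; return the vector."""
    C = np.asarray(C, dtype=float)
    if C.ndim == 2:
        if not np.allclose(C, np.diag(np.diag(C))):
            raise ValueError(f"{name} must be diagonal")
        C = np.diag(C)
    if np.any(C <= 0) or not np.all(np.isfinite(C)):
        raise ValueError(f"{name} must have strictly positive finite diagonal")
    return C


def solve_sylvester_kron(
    X: np.ndarray, Y: np.ndarray, K: np.ndarray, mu: float
) -> np.ndarray:
    """Solve ``X'X B + mu * B K = X'Y`` by forming the dense (sp x sp) system.

    Reference oracle only: memory is O((sp)^2), so this is reserved for
    cross-checking the SVD route on small instances.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    K = np.asarray(K, float)
    p = X.shape[1]
    s = Y.shape[1]
    A = np.kron(np.eye(s), X.T @ X) + mu * np.kron(K.T, np.eye(p))
    rhs = (X.T @ Y).flatten(order="F")
    vecB = np.linalg.solve(A, rhs)  # raises LinAlgError if singular
    return vecB.reshape((p, s), order="F")


def _thin_svd(X: np.ndarray):
    U, g, Vt = np.linalg.svd(np.asarray(X, float), full_matrices=False)
    keep = g > SVD_RTOL * (g[0] if g.size else 1.0)
    return U[:, keep], g[keep], Vt[keep].T


def solve_sylvester_svd(
    X: np.ndarray,
    Y: np.ndarray,
    C: np.ndarray,
    Omega0: np.ndarray,
    mu: float,
) -> np.ndarray:
    """Solve the coefficient-update Sylvester equation via the SVD of X.

    With the thin SVD ``X = U1 diag(g) V1'`` (rank r) and the change of
    variables ``Btilde = V1' B``, the normal equation
    ``X'X B + mu B C Omega0^{-1} = X'Y`` reduces to
    ``diag(g^2) Btilde + mu Btilde K = S`` with ``K = C Omega0^{-1}`` and
    ``S = V1' X' Y``.  K is diagonalized through the symmetric similarity
    ``C^{1/2} Omega0^{-1} C^{1/2} = W L W'`` (numerically stable: the
    eigenproblem is symmetric positive definite), in whose eigenbasis the
    columns decouple into diagonal solves.  The component of B outside the
    row space of X is exactly zero, so ``mu = 0`` returns the minimum-norm
    least-squares solution.

    Parameters
    ----------
    C : positive diagonal (matrix or its diagonal vector), shape (s,) or (s,s)
    Omega0 : SPD matrix or positive diagonal vector, shape (s,s) or (s,)
    mu : non-negative scalar (``n * lambda2`` in the estimators)
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    U1, g, V1 = _thin_svd(X)
    S = g[:, None] * (U1.T @ Y)  # = V1' X' Y
    if mu == 0:
        return V1 @ (S / (g * g)[:, None])

    c = _as_diag_vector(C)
    Omega0 = np.asarray(Omega0, float)
    if Omega0.ndim == 1:
        if np.any(Omega0 <= 0):
            raise ValueError("diagonal Omega0 must be positive")
        om_inv = np.diag(1.0 / Omega0)
    else:
        if not np.allclose(Omega0, Omega0.T, atol=SYM_TOL):
            raise ValueError("Omega0 must be symmetric")
        try:
            cf = sla.cho_factor(Omega0)
        except np.linalg.LinAlgError as e:  # pragma: no cover - scipy raises its own
            raise ValueError("Omega0 must be positive definite") from e
        except sla.LinAlgError as e:
            raise ValueError("Omega0 must be positive definite") from e
        om_inv = sla.cho_solve(cf, np.eye(Omega0.shape[0]))

    sc = np.sqrt(c)
    M = sc[:, None] * om_inv * sc[None, :]
    M = 0.5 * (M + M.T)
    lam, W = np.linalg.eigh(M)
    if lam[0] <= 0:
        raise ValueError("C * Omega0^{-1} similarity is not positive definite")
    # K = T diag(lam) T^{-1} with T = diag(sqrt(c)) W
    T = sc[:, None] * W
    Tinv = W.T * (1.0 / sc)[None, :]
    Z = (S @ T) / ((g * g)[:, None] + mu * lam[None, :])
    Btilde = Z @ Tinv
    return V1 @ Btilde


def spd_principal_sqrt(M: np.ndarray, clip_tol: float = 1e-10) -> np.ndarray:
    """Principal square root of a symmetric positive semidefinite matrix.

    Eigenvalues in [-clip_tol, 0) are clipped to zero; more negative ones
    raise, as do inputs that are asymmetric beyond tolerance.
    """
    M = np.asarray(M, float)
    if not np.allclose(M, M.T, atol=SYM_TOL * (1.0 + np.abs(M).max(initial=0.0))):
        raise ValueError("input must be symmetric")
    lam, V = np.linalg.eigh(0.5 * (M + M.T))
    if lam[0] < -clip_tol * (1.0 + abs(lam[-1])):
        raise ValueError(f"input not PSD: min eigenvalue {lam[0]:.3e}")
    lam = np.clip(lam, 0.0, None)
    return (V * np.sqrt(lam)[None, :]) @ V.T


def solve_precision_riccati(P: np.ndarray, lambda1: float) -> np.ndarray:
    """Closed-form SPD root of ``2*lambda1*Omega^2 + P*Omega - I = 0``.

    For symmetric PSD ``P`` and ``lambda1 > 0`` the unique SPD solution is

        Omega = ( (P^2 + 8*lambda1*I)^{1/2} - P ) / (4*lambda1)

    the matrix analogue of the positive scalar root
    ``(-p + sqrt(p^2 + 8*lambda)) / (4*lambda)``.  ``P`` and the square-root
    factor share an eigenbasis, so the plug-back residual vanishes to
    rounding error.  The ``lambda1 = 0`` limit is a plain inverse and must be
    handled by the caller (it requires a strictly PD ``P``).
    """
    if lambda1 <= 0:
        raise ValueError("lambda1 must be strictly positive")
    P = np.asarray(P, float)
    s = P.shape[0]
    R = spd_principal_sqrt(P @ P + 8.0 * lambda1 * np.eye(s))
    Omega = (R - P) / (4.0 * lambda1)
    return 0.5 * (Omega + Omega.T)


def invert_spd(P: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive definite matrix (Cholesky route)."""
    P = np.asarray(P, float)
    try:
        cf = sla.cho_factor(0.5 * (P + P.T))
    except (np.linalg.LinAlgError, sla.LinAlgError) as e:
        raise np.linalg.LinAlgError("matrix is not positive definite") from e
    Om = sla.cho_solve(cf, np.eye(P.shape[0]))
    return 0.5 * (Om + Om.T)


class GlassoConvergenceError(RuntimeError):
    """Raised when the graphical-lasso KKT certificate fails."""


def solve_precision_glasso(
    P: np.ndarray,
    lambda1: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    mode: str = "lars",
) -> np.ndarray:
    """L1-penalized sparse precision estimate (graphical lasso).

    Minimizes ``Tr(P Omega) - log|Omega| + lambda1 * sum_{i!=j} |omega_ij|``
    (diagonal unpenalized).  The numerical solver is delegated to
    scikit-learn, but the KKT stationarity certificate is verified here:
    off-diagonal ``|(Omega^{-1} - P)_ij| <= lambda1 + tol_kkt`` and
    ``(Omega^{-1})_ii == P_ii`` within tolerance.  ``lambda1 = 0`` returns
    the unpenalized MLE ``P^{-1}`` (PD required).  The default LARS inner
    solver meets the stationarity conditions to machine precision on
    ill-conditioned residual covariances where coordinate descent stalls.
    """
    P = np.asarray(P, float)
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    if not np.allclose(P, P.T, atol=SYM_TOL * (1.0 + np.abs(P).max(initial=0.0))):
        raise ValueError("P must be symmetric")
    P = 0.5 * (P + P.T)
    if lambda1 == 0:
        return invert_spd(P)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            cov, prec = _sk_graphical_lasso(
                P, alpha=lambda1, mode=mode, tol=tol, max_iter=max_iter
            )
    except FloatingPointError as e:
        raise GlassoConvergenceError(f"graphical lasso failed: {e}") from e
    prec = 0.5 * (prec + prec.T)
    # KKT certificate owned here (cov is the solver's Omega^{-1})
    gap = cov - P
    off = gap - np.diag(np.diag(gap))
    if np.abs(off).max(initial=0.0) > lambda1 + GLASSO_KKT_TOL:
        raise GlassoConvergenceError(
            "KKT violation: max off-diagonal |Omega^-1 - P| = "
            f"{np.abs(off).max():.3e} > lambda1 + {GLASSO_KKT_TOL:g} "
            f"(lambda1={lambda1}, max_iter={max_iter})"
        )
    if np.abs(np.diag(gap)).max(initial=0.0) > GLASSO_KKT_TOL:
        raise GlassoConvergenceError(
            "KKT violation on the unpenalized diagonal: "
            f"max |(Omega^-1)_ii - P_ii| = {np.abs(np.diag(gap)).max():.3e}"
        )
    return prec


def _chol_logdet(Omega: np.ndarray) -> float:
    try:
        L = np.linalg.cholesky(0.5 * (Omega + Omega.T))
    except np.linalg.LinAlgError as e:
        raise ValueError("Omega must be positive definite") from e
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def negative_log_likelihood(
    B: np.ndarray, Omega: np.ndarray, X: np.ndarray, Y: np.ndarray
) -> float:
    """Gaussian negative log-likelihood (up to constants).

    ``Tr[(1/n)(Y - XB)'(Y - XB) Omega] - log|Omega|`` for row-wise i.i.d.
    errors with precision ``Omega``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    R = Y - X @ np.asarray(B, float)
    P = (R.T @ R) / n
    return float(np.sum(P * Omega)) - _chol_logdet(np.asarray(Omega, float))


def penalized_objective(
    B: np.ndarray,
    Omega: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    hp: HyperParams,
    variant: str,
    zeta: float = 0.0,
) -> float:
    """Full penalized objective for either mixed-norm variant.

    variant "l1": nll + lambda1 * sum_{i!=j} |omega_ij| + lambda2 * ||B'||_{2,1}
    variant "l2": nll + lambda1 * ||Omega||_F^2      + lambda2 * ||B'||_{2,1}

    ``zeta > 0`` evaluates the smoothed L2,1 penalty
    ``sum_j sqrt(||B_col_j||^2 + zeta)`` actually descended by the IRLS.
    """
    Omega = np.asarray(Omega, float)
    nll = negative_log_likelihood(B, Omega, X, Y)
    if zeta > 0:
        Bc = np.asarray(B, float)
        pen_b = float(np.sum(np.sqrt(np.sum(Bc * Bc, axis=0) + zeta)))
    else:
        pen_b = l21_norm(np.asarray(B, float).T)
    if variant == "l1":
        off = Omega - np.diag(np.diag(Omega))
        pen_o = float(np.sum(np.abs(off)))
    elif variant == "l2":
        pen_o = float(np.sum(Omega * Omega))
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'l1' or 'l2'")
    return nll + hp.lambda1 * pen_o + hp.lambda2 * pen_b
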