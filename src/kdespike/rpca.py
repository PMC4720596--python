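"""Robust principal component analysis for complex matrices.

Solves the principal component pursuit problem

    min_{L,S}  ||L||_* + lambda ||S||_1   subject to   M = L + S

with the inexact augmented Lagrange multiplier (ALM) scheme: alternating
singular-value thresholding for the low-rank component ``L`` and
magnitude (complex) soft thresholding for the sparse component ``S``,
with a geometrically growing penalty ``mu``.  Both norms use their
natural complex extensions: the L1 norm is the sum of entry moduli and
the nuclear norm is the sum of (real, nonnegative) singular values of
the complex SVD, so the shrinkage steps preserve the phase of every
entry and singular vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg

__all__ = [
    "SolverConfig",
    "RPCAResult",
    "complex_soft_threshold",
    "singular_value_threshold",
    "rpca_decompose",
]

# mu is capped at mu0 * MU_CAP_FACTOR, as in the reference inexact ALM solver
MU_CAP_FACTOR = 1e7


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of the inexact ALM solver.

    Parameters
    ----------
    lambda_eff : float
        Weight of the L1 term (``kappa * lambda`` in the despiking
        context).  Must be positive.
    tol : float
        Stopping threshold on the relative constraint residual
        ``||M - L - S||_F / ||M||_F``.
    max_iter : int
        Iteration cap.  Exceeding it yields ``converged=False`` in the
        result, not an exception.
    mu0 : float or "auto"
        Initial penalty.  ``"auto"`` uses ``1.25 / ||M||_2``.
    rho : float
        Penalty growth factor, ``> 1``.
    svd_method : {"full", "truncated"}
        ``"full"`` computes an economy SVD each iteration.
        ``"truncated"`` predicts the active rank from the previous
        iteration and uses a partial SVD when the prediction is small,
        falling back to the full SVD whenever the prediction could be
        too small.
    """

    lambda_eff: float
    tol: float = 1e-7
    max_iter: int = 1000
    mu0: float | str = "auto"
    rho: float = 1.5
    svd_method: str = "full"

    def __post_init__(self) -> None:
        if not self.lambda_eff > 0:
            raise ValueError("lambda_eff must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.rho > 1:
            raise ValueError("rho must be > 1")
        if self.mu0 != "auto" and not float(self.mu0) > 0:
            raise ValueError("mu0 must be positive or 'auto'")
        if self.svd_method not in ("full", "truncated"):
            raise ValueError("svd_method must be 'full' or 'truncated'")


@dataclass
class RPCAResult:
    """Outcome of one RPCA decomposition ``M = L + S (+ residual)``."""

    L: np.ndarray
    S: np.ndarray
    n_iter: int
    converged: bool
    final_residual: float
    rank_L: int


def complex_soft_threshold(z, tau: float):
    """Proximal operator of ``tau * ||.||_1`` for complex arguments.

    Shrinks the modulus of every entry by ``tau`` (to exactly zero when
    ``|z| <= tau``) while preserving its phase.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    z = np.asarray(z)
    mag = np.abs(z)
    shrunk = np.maximum(mag - tau, 0.0)
    scale = np.divide(shrunk, mag, out=np.zeros_like(mag), where=mag > 0)
    return z * scale


def singular_value_threshold(X: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of ``tau * ||.||_*``: shrink singular values by tau.

    Returns ``U diag(max(s - tau, 0)) V^H`` for the economy SVD of X.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("input must be finite")
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vh


def _partial_svd(X: np.ndarray, k: int):
    """Top-k SVD via scipy (ARPACK), sorted by decreasing singular value."""
    U, s, Vh = scipy.sparse.linalg.svds(X, k=k)
    order = np.argsort(s)[::-1]
    return U[:, order], s[order], Vh[order]


def rpca_decompose(M: np.ndarray, config: SolverConfig) -> RPCAResult:
    """Decompose a complex matrix into low-rank plus sparse components.

    Deterministic for fixed inputs: the solver contains no randomness.
    Non-convergence within ``config.max_iter`` is reported through
    ``RPCAResult.converged``, never raised.
    """
    M = np.asarray(M, dtype=np.complex128)
    if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 1:
        raise ValueError("M must be a 2-D matrix with at least one row and column")
    if not np.all(np.isfinite(M)):
        raise ValueError("M must be finite")

    norm_fro = np.linalg.norm(M)
    if norm_fro == 0.0:
        Z = np.zeros_like(M)
        return RPCAResult(L=Z, S=Z.copy(), n_iter=0, converged=True,
                          final_residual=0.0, rank_L=0)

    lam = config.lambda_eff
    norm_two = np.linalg.norm(M, 2)
    dual_norm = max(norm_two, np.max(np.abs(M)) / lam)
    Y = M / dual_norm
    mu = 1.25 / norm_two if config.mu0 == "auto" else float(config.mu0)
    mu_bar = mu * MU_CAP_FACTOR
    rho = config.rho

    m, n = M.shape
    min_dim = min(m, n)
    L = np.zeros_like(M)
    S = np.zeros_like(M)
    sv_pred = min(10, min_dim)  # rank prediction for the truncated path

    converged = False
    residual = np.inf
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        S = complex_soft_threshold(M - L + Y / mu, lam / mu)
        G = M - S + Y / mu

        use_partial = (
            config.svd_method == "truncated" and 1 <= sv_pred < min_dim // 5
        )
        if use_partial:
            U, s, Vh = _partial_svd(G, sv_pred)
            if s[-1] > 1.0 / mu:  # prediction too small; redo exactly
                use_partial = False
        if not use_partial:
            U, s, Vh = np.linalg.svd(G, full_matrices=False)

        svp = int(np.count_nonzero(s > 1.0 / mu))
        if svp < sv_pred:
            sv_pred = min(svp + 1, min_dim)
        else:
            sv_pred = min(svp + int(round(0.05 * min_dim)) + 1, min_dim)
        L = (U[:, :svp] * (s[:svp] - 1.0 / mu)) @ Vh[:svp]

        Z = M - L - S
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)

        residual = float(np.linalg.norm(Z) / norm_fro)
        if residual < config.tol:
            converged = True
            break

    return RPCAResult(
        L=L,
        S=S,
        n_iter=n_iter,
        converged=converged,
        final_residual=residual,
        rank_L=int(np.linalg.matrix_rank(L)),
    )
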