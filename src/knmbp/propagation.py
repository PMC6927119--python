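"""Bidirectional label propagation over miRNA and disease similarity graphs.

Predicted scores F stay close to the (corrected) interaction matrix Y while
being smooth along both similarity graphs, through the convex objective

    min_F ||F - Y||_F^2
          + lambda_m/2 * tr(F^T L_m F) + lambda_d/2 * tr(F L_d F^T)

with L = I - D^(-1/2) S D^(-1/2) the symmetrically normalized Laplacians of
the miRNA (rows) and disease (columns) similarity matrices.  The gradient

    2 (F - Y) + lambda_m L_m F + lambda_d F L_d

vanishes at the unique minimizer, the solution of the Sylvester-type system
(2 I + lambda_m L_m) F + lambda_d F L_d = 2 Y.  Two solvers are provided:
an AdaGrad iteration (per-element adaptive step sizes) and an exact
eigendecomposition-based solver; both converge to the same optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PropagationParams:
    """Solver settings for the bidirectional propagation objective."""

    lambda_m: float = 1.0
    lambda_d: float = 1.0
    eta0: float = 0.1
    tol: float = 1e-6
    max_iter: int = 1000
    adagrad_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_m < 0 or self.lambda_d < 0:
            raise ValueError("Laplacian weights must be >= 0")
        if self.eta0 <= 0 or self.tol <= 0:
            raise ValueError("eta0 and tol must be > 0")


def normalized_laplacian(s: np.ndarray) -> np.ndarray:
    """Symmetrically normalized Laplacian I - D^(-1/2) S D^(-1/2).

    Zero-degree rows are given unit degree so the normalization is defined;
    the result is symmetric PSD with eigenvalues in [0, 2].
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity must be symmetric")
    if (s < 0).any():
        raise ValueError("similarity must be nonnegative")
    d = s.sum(axis=1)
    d = np.where(d > 0, d, 1.0)
    inv_sqrt = 1.0 / np.sqrt(d)
    lap = np.eye(s.shape[0]) - inv_sqrt[:, None] * s * inv_sqrt[None, :]
    return 0.5 * (lap + lap.T)


def pairwise_smoothness(f: np.ndarray, s: np.ndarray) -> float:
    """Graph smoothness of row vectors as an explicit pairwise sum.

    Sum over unordered pairs {i, j} of s_ij * ||f_i/sqrt(d_i) - f_j/sqrt(d_j)||^2,
    which equals tr(F^T L F) for the normalized Laplacian of S.  Kept as the
    direct double loop: it exists to validate the Laplacian assembly.
    """
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    d = s.sum(axis=1)
    d = np.where(d > 0, d, 1.0)
    scaled = f / np.sqrt(d)[:, None]
    total = 0.0
    n = s.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            diff = scaled[i] - scaled[j]
            total += s[i, j] * float(diff @ diff)
    return total


def objective(
    f: np.ndarray,
    y: np.ndarray,
    lap_m: np.ndarray,
    lap_d: np.ndarray,
    params: PropagationParams,
) -> float:
    resid = f - y
    val = float((resid**2).sum())
    val += 0.5 * params.lambda_m * float(np.trace(f.T @ lap_m @ f))
    val += 0.5 * params.lambda_d * float(np.trace(f @ lap_d @ f.T))
    return val


def gradient(
    f: np.ndarray,
    y: np.ndarray,
    lap_m: np.ndarray,
    lap_d: np.ndarray,
    params: PropagationParams,
) -> np.ndarray:
    return 2.0 * (f - y) + params.lambda_m * (lap_m @ f) + params.lambda_d * (f @ lap_d)


def linear_solve(
    y: np.ndarray,
    lap_m: np.ndarray,
    lap_d: np.ndarray,
    params: PropagationParams,
) -> np.ndarray:
    """Exact minimizer via eigendecompositions of the two Laplacians.

    Diagonalizing L_m = U A U^T and L_d = V B V^T turns the stationarity
    system (2I + lambda_m L_m) F + lambda_d F L_d = 2Y into independent
    scalar equations in the eigenbasis.
    """
    am, um = np.linalg.eigh(lap_m)
    ad, ud = np.linalg.eigh(lap_d)
    rhs = um.T @ (2.0 * y) @ ud
    denom = 2.0 + params.lambda_m * am[:, None] + params.lambda_d * ad[None, :]
    return um @ (rhs / denom) @ ud.T


def adagrad_solve(
    y: np.ndarray,
    lap_m: np.ndarray,
    lap_d: np.ndarray,
    params: PropagationParams | None = None,
    return_history: bool = False,
):
    """Minimize the propagation objective by AdaGrad from F0 = Y.

    Per-element steps eta0 / sqrt(G + eps) with G the accumulated squared
    gradients; stops when the relative objective change drops below ``tol``.
    If the objective increases for 10 consecutive iterations, the base step
    is halved once; persistent divergence raises.
    """
    if params is None:
        params = PropagationParams()
    f = y.astype(float).copy()
    g_acc = np.zeros_like(f)
    eta = params.eta0
    prev_obj = objective(f, y, lap_m, lap_d, params)
    history = [prev_obj]
    bad_streak = 0
    halved = False
    for _ in range(params.max_iter):
        grad = gradient(f, y, lap_m, lap_d, params)
        g_acc += grad**2
        f = f - eta * grad / np.sqrt(g_acc + params.adagrad_eps)
        obj = objective(f, y, lap_m, lap_d, params)
        history.append(obj)
        if obj > prev_obj:
            bad_streak += 1
            if bad_streak >= 10:
                if halved:
                    raise RuntimeError("AdaGrad diverged even after halving the step size")
                eta *= 0.5
                halved = True
                bad_streak = 0
        else:
            bad_streak = 0
        if prev_obj > 0 and abs(prev_obj - obj) / max(prev_obj, 1e-30) < params.tol:
            prev_obj = obj
            break
        prev_obj = obj
    if return_history:
        return f, history
    return f
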