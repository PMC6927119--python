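"""Kernel-based neighbourhood similarity (KSNS).

Each entity's interaction profile is reconstructed from the other profiles
in a Gaussian-kernel feature space.  The reconstruction weights W minimize

    1/2 ||Phi(X) W - Phi(X)||_F^2
    + mu1/2 ||W o (1 - C)||_F^2 + mu2/2 ||W||_F^2,   W >= 0, diag(W) = 0,

where C marks, for every entity, its NK = floor(PN * N) nearest neighbours
under a base similarity (functional similarity for miRNAs, semantic
similarity for diseases): weights outside the neighbourhood are penalized by
mu1, and mu2 is a ridge term.  The problem is solved by the multiplicative
update

    W <- W o (K + mu1 * W o C) / (K W + mu1 W + mu2 W),

which preserves nonnegativity and the zero diagonal.  The converged weights
are degree-normalized, D^(-1/2) W^T D^(-1/2) with D the diagonal of column
sums, and symmetrized into the kernel neighbourhood similarity.
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import LabeledMatrix
from .errors import DegenerateInputError

EPS = 1e-12


def neighbor_indicator(s_base: np.ndarray | LabeledMatrix, pn: float) -> np.ndarray:
    """0/1 matrix marking each row's floor(PN*N) nearest entities (self excluded)."""
    s = s_base.values if isinstance(s_base, LabeledMatrix) else np.asarray(s_base)
    n = s.shape[0]
    if not 0.0 < pn <= 1.0:
        raise ValueError(f"PN must be in (0, 1], got {pn}")
    nk = int(np.floor(pn * n))
    c = np.zeros((n, n), dtype=float)
    if nk == 0:
        warnings.warn("floor(PN*N) = 0: empty neighbourhoods, C is all zero")
        return c
    nk = min(nk, n - 1)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, -s[i]))
        order = order[order != i][:nk]
        c[i, order] = 1.0
    return c


def gaussian_kernel(profiles: np.ndarray) -> np.ndarray:
    """Gaussian kernel of profile rows with self-tuned bandwidth.

    The bandwidth is gamma = sum_i ||x_i||^2 / N, so the kernel scale adapts
    to the overall profile mass; all-zero input is degenerate.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two profile rows")
    sq = np.einsum("ij,ij->i", x, x)
    gamma = sq.sum() / x.shape[0]
    if gamma <= 0:
        raise DegenerateInputError("all profiles are zero; kernel bandwidth is 0")
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.clip(d2, 0.0, None, out=d2)
    k = np.exp(-d2 / gamma)
    k = 0.5 * (k + k.T)
    np.fill_diagonal(k, 1.0)
    return k


def ksns_objective(w: np.ndarray, kernel: np.ndarray, c: np.ndarray, mu1: float, mu2: float) -> float:
    """Value of the KSNS objective (without the sum-to-one constraint)."""
    resid = w - np.eye(w.shape[0])
    fit = 0.5 * float(np.trace(resid.T @ kernel @ resid))
    pen1 = 0.5 * mu1 * float(((w * (1.0 - c)) ** 2).sum())
    pen2 = 0.5 * mu2 * float((w**2).sum())
    return fit + pen1 + pen2


def ksns_optimize(
    kernel: np.ndarray,
    c: np.ndarray,
    mu1: float,
    mu2: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    callback=None,
) -> np.ndarray:
    """Minimize the KSNS objective by multiplicative updates.

    Starts from the uniform off-diagonal matrix W0 = 1/(N-1); the update is
    a ratio of the negative and positive parts of the gradient, so zeros
    (in particular the diagonal) are preserved and W stays nonnegative.
    Stops when the largest relative change of any entry drops below ``tol``.
    """
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("mu1 and mu2 must be > 0")
    n = kernel.shape[0]
    if kernel.shape != (n, n) or c.shape != (n, n):
        raise ValueError("kernel and neighbour indicator must be square and conformable")
    w = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(w, 0.0)
    for _ in range(max_iter):
        numer = kernel + mu1 * (w * c)
        denom = kernel @ w + (mu1 + mu2) * w + EPS
        w_new = w * numer / denom
        np.fill_diagonal(w_new, 0.0)
        if callback is not None:
            callback(w_new)
        delta = np.abs(w_new - w) / (np.abs(w) + EPS)
        w = w_new
        if delta.max() < tol:
            break
    return w


def normalize_weight(w: np.ndarray) -> np.ndarray:
    """Degree-normalize and symmetrize converged weights into a similarity.

    SI = D^(-1/2) W^T D^(-1/2) with D = diag of column sums (zero sums are
    replaced by 1), followed by (SI + SI^T)/2 so downstream Laplacians are
    well defined.
    """
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    d = w.sum(axis=0)
    d = np.where(d > 0, d, 1.0)
    inv_sqrt = 1.0 / np.sqrt(d)
    si = inv_sqrt[:, None] * w.T * inv_sqrt[None, :]
    return 0.5 * (si + si.T)


def kernel_neighborhood_similarity(
    profiles: np.ndarray,
    s_base: np.ndarray | LabeledMatrix,
    pn: float = 0.5,
    mu1: float = 4.0,
    mu2: float = 4.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Profiles + base similarity -> symmetric kernel neighbourhood similarity."""
    c = neighbor_indicator(s_base, pn)
    kernel = gaussian_kernel(profiles)
    w = ksns_optimize(kernel, c, mu1, mu2, tol=tol, max_iter=max_iter)
    return normalize_weight(w)
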