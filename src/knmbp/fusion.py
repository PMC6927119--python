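"""Diffusion-based network fusion (diffusion component analysis style).

Several similarity networks over the same entities are fused by comparing
the entities' diffusion states: the stationary random-walk-with-restart
distribution started from each node.  The log of the (averaged) diffusion
states is factored by a truncated SVD into low-dimensional node vectors,
and the inner products of those vectors, rescaled to [0, 1], give the fused
similarity.  This condenses each network's global connectivity pattern into
one embedding, so evidence from the input networks is integrated without
per-network weights.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import LabeledMatrix


def rwr_diffusion(s: np.ndarray | LabeledMatrix, restart_p: float = 0.5) -> np.ndarray:
    """Stationary random-walk-with-restart distributions of every node.

    The transition matrix is the row-normalized similarity (isolated nodes
    get a uniform row); Q = p (I - (1-p) P)^(-1) is row-stochastic.
    """
    sv = s.values if isinstance(s, LabeledMatrix) else np.asarray(s, dtype=float)
    if not 0.0 < restart_p <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {restart_p}")
    if (sv < 0).any():
        raise ValueError("similarity must be nonnegative")
    n = sv.shape[0]
    rows = sv.sum(axis=1)
    p = np.where(rows[:, None] > 0, sv / np.where(rows[:, None] > 0, rows[:, None], 1.0), 1.0 / n)
    q = restart_p * np.linalg.inv(np.eye(n) - (1.0 - restart_p) * p)
    return q


@dataclass
class Embedding:
    """Rank-d factors of the log diffusion-state matrix."""

    node_vectors: np.ndarray
    context_vectors: np.ndarray
    singular_values: np.ndarray

    @property
    def dim(self) -> int:
        return self.node_vectors.shape[1]


def dca_embed(
    states: list[np.ndarray],
    dim: int,
    eps: float | None = None,
    mode: str = "average",
) -> Embedding:
    """Factor log diffusion states into rank-``dim`` node/context vectors.

    ``mode='average'`` averages the diffusion states across networks before
    the log (equal-weight integration); ``'concat'`` column-concatenates the
    per-network log matrices instead.  ``eps`` (default 1/N) floors the log.
    """
    if not states:
        raise ValueError("need at least one diffusion state matrix")
    n = states[0].shape[0]
    for q in states:
        if q.shape != (n, n):
            raise ValueError("all diffusion states must share the node set")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if eps is None:
        eps = 1.0 / n
    if mode == "average":
        logs = np.log(np.mean(states, axis=0) + eps)
    elif mode == "concat":
        logs = np.hstack([np.log(q + eps) for q in states])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d_max = min(logs.shape)
    if dim > d_max:
        warnings.warn(f"dim={dim} exceeds matrix rank bound {d_max}; clamping")
        dim = d_max
    u, sing, vt = np.linalg.svd(logs, full_matrices=False)
    root = np.sqrt(sing[:dim])
    return Embedding(u[:, :dim] * root, vt[:dim].T * root, sing[:dim])


def fuse_similarity(
    networks: list[LabeledMatrix],
    dim: int | None = None,
    restart_p: float = 0.5,
    mode: str = "average",
) -> LabeledMatrix:
    """Fuse similarity networks over a common label set into one matrix.

    The fused matrix is node_vectors @ node_vectors.T from the diffusion
    embedding, min-max rescaled to [0, 1], symmetrized, with unit diagonal.
    Default embedding dimension is min(100, N-1).
    """
    if not networks:
        raise ValueError("need at least one network to fuse")
    labels = networks[0].labels
    n = len(labels)
    mats = [networks[0].values]
    for net in networks[1:]:
        mats.append(net.reorder(labels).values)
    if dim is None:
        dim = min(100, n - 1)
    states = [rwr_diffusion(m, restart_p) for m in mats]
    emb = dca_embed(states, dim, mode=mode)
    fused = emb.node_vectors @ emb.node_vectors.T
    fused = 0.5 * (fused + fused.T)
    lo, hi = fused.min(), fused.max()
    if hi > lo:
        fused = (fused - lo) / (hi - lo)
    else:
        fused = np.zeros_like(fused)
    np.fill_diagonal(fused, 1.0)
    return LabeledMatrix(labels, fused)
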