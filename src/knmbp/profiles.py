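"""Weighted k-nearest-neighbour correction of sparse interaction profiles (WKNNP).

Known miRNA-disease interaction matrices are extremely sparse, and an absent
entry mostly means "untested" rather than "no interaction".  Each entity's
profile (matrix row for a miRNA, column for a disease) is therefore enriched
by a decayed, similarity-weighted average of its K most similar neighbours'
profiles:

    profile_hat(i) = (1 / Q_i) * sum_{k=1..K} alpha^(k-1) * S(i, n_k) * profile(n_k)
    Q_i            = sum_{j in N(i)} S(i, j)

with neighbours ranked by descending similarity.  The row- and column-wise
corrections are averaged and combined with the raw matrix by an elementwise
maximum, so observed interactions are never down-weighted.
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import InteractionMatrix, LabeledMatrix


def _neighbor_order(sim_row: np.ndarray, self_idx: int) -> np.ndarray:
    """Indices of all other entities by descending similarity, ties by index."""
    n = sim_row.shape[0]
    order = np.lexsort((np.arange(n), -sim_row))
    return order[order != self_idx]


def wknnp_profiles(
    profiles: np.ndarray,
    similarity: np.ndarray,
    k: int = 15,
    alpha: float = 0.8,
    weight_mode: str = "similarity",
) -> np.ndarray:
    """WKNNP correction of a profile matrix (one entity per row).

    ``weight_mode='similarity'`` weights neighbour k by alpha^(k-1)*S(i, n_k)
    (the default); ``'plain'`` uses alpha^(k-1) alone, with similarities
    entering only through the normalizer Q_i.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if weight_mode not in ("similarity", "plain"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    n = profiles.shape[0]
    if similarity.shape != (n, n):
        raise ValueError("similarity shape does not match number of profiles")
    if k >= n:
        warnings.warn(f"K={k} >= {n} entities; truncating to {n - 1}")
        k = n - 1
    out = np.zeros_like(profiles, dtype=float)
    decay = alpha ** np.arange(k)
    for i in range(n):
        nbrs = _neighbor_order(similarity[i], i)[:k]
        sims = similarity[i, nbrs]
        q = sims.sum()
        if q <= 0:
            continue
        w = decay * sims if weight_mode == "similarity" else decay
        out[i] = (w @ profiles[nbrs]) / q
    return out


def wknnp_axis(
    x: np.ndarray,
    s_side: np.ndarray | LabeledMatrix,
    k: int = 15,
    alpha: float = 0.8,
    axis: int = 0,
    weight_mode: str = "similarity",
) -> np.ndarray:
    """Apply the WKNNP correction along rows (axis=0) or columns (axis=1)."""
    s = s_side.values if isinstance(s_side, LabeledMatrix) else np.asarray(s_side)
    x = np.asarray(x, dtype=float)
    if axis == 0:
        return wknnp_profiles(x, s, k=k, alpha=alpha, weight_mode=weight_mode)
    if axis == 1:
        return wknnp_profiles(x.T, s, k=k, alpha=alpha, weight_mode=weight_mode).T
    raise ValueError(f"axis must be 0 or 1, got {axis}")


def combine_profiles(x: np.ndarray, x_m: np.ndarray, x_d: np.ndarray) -> np.ndarray:
    """Elementwise max of the raw matrix and the mean of the two corrections."""
    x, x_m, x_d = (np.asarray(a, dtype=float) for a in (x, x_m, x_d))
    if not (x.shape == x_m.shape == x_d.shape):
        raise ValueError(
            f"shape mismatch: {x.shape}, {x_m.shape}, {x_d.shape}"
        )
    return np.maximum(x, 0.5 * (x_m + x_d))


def modified_profile_matrix(
    interactions: InteractionMatrix,
    sim_mirna: LabeledMatrix,
    sim_disease: LabeledMatrix,
    k: int = 15,
    alpha: float = 0.8,
    weight_mode: str = "similarity",
) -> InteractionMatrix:
    """Full WKNNP pass over an interaction matrix, labels checked on both axes."""
    if sim_mirna.labels != interactions.row_labels:
        raise ValueError("miRNA similarity labels do not match interaction rows")
    if sim_disease.labels != interactions.col_labels:
        raise ValueError("disease similarity labels do not match interaction columns")
    x = interactions.values
    x_m = wknnp_axis(x, sim_mirna, k=k, alpha=alpha, axis=0, weight_mode=weight_mode)
    x_d = wknnp_axis(x, sim_disease, k=k, alpha=alpha, axis=1, weight_mode=weight_mode)
    return interactions.with_values(combine_profiles(x, x_m, x_d))
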