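"""Cross-validation schemes, threshold-grid ROC/AUC, grid search, Fisher test.

Three 5-fold cross-validation designs probe different generalization modes
of a bipartite interaction predictor: masking individual pairs (CV over all
interactions), whole miRNA rows (new miRNAs), or whole disease columns (new
diseases).  Test scores are min-max normalized, the unit interval is divided
into 1000 equal threshold steps, TPR/FPR are averaged across folds at each
threshold, and the AUC is the trapezoidal area under the mean curve; AUCs
from repeated runs with different seeds are averaged.  A ranked candidate
list is checked for enrichment of confirmed interactions in its top versus
bottom group by a two-sided Fisher's exact test.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InteractionMatrix

CV_MODES = ("pairs", "mirnas", "diseases")


@dataclass
class CVPlan:
    """Fold assignment for one cross-validation run."""

    mode: str
    k: int
    seed: int
    folds: list[np.ndarray]  # pairs: flat matrix indices; otherwise row/col indices
    shape: tuple[int, int]

    def train_mask(self, fold: int) -> np.ndarray:
        """Boolean matrix: True where an entry belongs to the training set."""
        keep = np.ones(self.shape, dtype=bool)
        idx = self.folds[fold]
        if self.mode == "pairs":
            keep.flat[idx] = False
        elif self.mode == "mirnas":
            keep[idx, :] = False
        else:
            keep[:, idx] = False
        return keep


def cv_folds(
    y: InteractionMatrix | np.ndarray, mode: str, k: int = 5, seed: int = 0
) -> CVPlan:
    """Partition pairs, miRNA rows or disease columns into k balanced folds.

    In ``pairs`` mode the known (1) and unknown (0) entries are stratified
    separately so every fold sees the same class balance.
    """
    values = y.values if isinstance(y, InteractionMatrix) else np.asarray(y)
    if mode not in CV_MODES:
        raise ValueError(f"mode must be one of {CV_MODES}, got {mode!r}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    if mode == "pairs":
        flat = values.ravel()
        ones = np.flatnonzero(flat == 1)
        zeros = np.flatnonzero(flat != 1)
        if min(len(ones), len(zeros)) < k and min(len(ones), len(zeros)) > 0:
            warnings.warn("fewer units than folds in one class; folds will be uneven")
        rng.shuffle(ones)
        rng.shuffle(zeros)
        folds = [
            np.sort(np.concatenate([part_o, part_z]))
            for part_o, part_z in zip(np.array_split(ones, k), np.array_split(zeros, k))
        ]
    else:
        n = values.shape[0] if mode == "mirnas" else values.shape[1]
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} available units")
        units = rng.permutation(n)
        folds = [np.sort(part) for part in np.array_split(units, k)]
    return CVPlan(mode, k, seed, folds, values.shape)


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """Rescale scores to span exactly [0, 1]; constant input maps to all-zero."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        warnings.warn("constant scores: min-max normalization maps everything to 0")
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


@dataclass
class ROCResult:
    """Threshold-grid ROC averaged over folds."""

    thresholds: np.ndarray
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray
    auc: float
    fold_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _fold_rates(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    # a score >= threshold is called positive (both grid endpoints included)
    calls = scores[None, :] >= thresholds[:, None]
    tpr = calls[:, pos].sum(axis=1) / n_pos
    fpr = calls[:, ~pos].sum(axis=1) / n_neg
    return tpr, fpr


def roc_auc(
    scores,
    labels,
    n_thresholds: int = 1000,
    normalize: bool = True,
) -> ROCResult:
    """ROC/AUC over a 1000-step threshold grid, averaged across folds.

    ``scores``/``labels`` may be single arrays or per-fold lists.  Scores of
    each fold are min-max normalized (unless ``normalize=False``), rates are
    computed at each of n_thresholds+1 grid points spanning [0, 1] and
    averaged across folds, and the AUC is the trapezoidal area under the
    mean (FPR, TPR) curve.
    """
    if isinstance(scores, np.ndarray) and scores.ndim == 1:
        scores, labels = [scores], [labels]
    thresholds = np.linspace(0.0, 1.0, n_thresholds + 1)
    curves = []
    for sc, lab in zip(scores, labels):
        sc = np.asarray(sc, dtype=float)
        lab = np.asarray(lab)
        if normalize:
            sc = minmax_normalize(sc)
        curves.append(_fold_rates(sc, lab, thresholds))
    mean_tpr = np.mean([c[0] for c in curves], axis=0)
    mean_fpr = np.mean([c[1] for c in curves], axis=0)
    # thresholds ascend, so rates descend; integrate with FPR ascending
    auc = float(np.trapezoid(mean_tpr[::-1], mean_fpr[::-1]))
    return ROCResult(thresholds, mean_tpr, mean_fpr, auc, curves)


def mean_seed_auc(aucs) -> float:
    """Final AUC: the mean across repetitions run with different seeds."""
    return float(np.mean(list(aucs)))


def fisher_top_bottom(
    ranked_candidates, confirmed_set, group_size: int = 20
):
    """Top-versus-bottom confirmation enrichment of a ranked candidate list.

    ``ranked_candidates`` must be ordered by descending predicted score.
    The first and last ``group_size`` candidates form the Top and Bottom
    groups; returns the 2x2 table [[top_conf, top_unconf], [bot_conf,
    bot_unconf]] and the two-sided Fisher's exact p-value (sum of all
    hypergeometric tables at most as probable as the observed one).
    """
    ranked = list(ranked_candidates)
    if len(ranked) < 2 * group_size:
        raise ValueError(
            f"need at least {2 * group_size} candidates, got {len(ranked)}"
        )
    confirmed_set = set(confirmed_set)
    top = ranked[:group_size]
    bottom = ranked[-group_size:]
    t_conf = sum(1 for c in top if c in confirmed_set)
    b_conf = sum(1 for c in bottom if c in confirmed_set)
    table = np.array(
        [[t_conf, group_size - t_conf], [b_conf, group_size - b_conf]], dtype=int
    )
    p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p_value


def grid_search(param_grid: dict, cv_runner) -> tuple[dict, pd.DataFrame]:
    """Exhaustive AUC evaluation of a parameter grid.

    ``cv_runner`` maps a parameter dict to an AUC.  Returns the arg-max
    combination and the full table (one row per combination), which supports
    marginal max/mean/min sensitivity summaries.
    """
    names = list(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        params = dict(zip(names, combo))
        rows.append({**params, "auc": float(cv_runner(params))})
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax()]
    best_params = {n: best[n] for n in names}
    return best_params, table


def marginal_summary(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Max/mean/min AUC over the grid cells fixing the ``by`` parameters."""
    return (
        table.groupby(by)["auc"].agg(["max", "mean", "min"]).reset_index()
    )
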