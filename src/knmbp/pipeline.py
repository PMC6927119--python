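"""End-to-end prediction pipeline and cross-validated evaluation.

The full method chains the stage modules:

1. semantic similarity matrices (one per annotation corpus) are fused into
   the disease similarity SS_d; target sets + gene network give the miRNA
   functional similarity SF_m;
2. the observed interaction matrix is corrected by WKNNP into X-hat;
3. kernel neighbourhood similarities SI_m (rows of X-hat, neighbourhoods
   from SF_m) and SI_d (columns, neighbourhoods from SS_d) are computed;
4. SF_m is fused with SI_m into S_m, SS_d with SI_d into S_d;
5. bidirectional Laplacian propagation of X-hat over S_m and S_d yields
   the score matrix F.

Cross-validation recomputes steps 2-5 from the training matrix of every
fold, so no interaction-derived quantity ever sees a test entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import InteractionMatrix, LabeledMatrix
from .evaluation import CVPlan, ROCResult, cv_folds, mean_seed_auc, roc_auc
from .fusion import fuse_similarity
from .ksns import kernel_neighborhood_similarity
from .ontology import CorpusAnnotation, DiseaseDAG, semantic_similarity_matrix
from .profiles import modified_profile_matrix
from .propagation import PropagationParams, adagrad_solve, linear_solve, normalized_laplacian


@dataclass
class KNMBPParams:
    """All tunable parameters of the pipeline with their default settings.

    K and alpha are the profile-correction constants fixed by the method
    (K=15 neighbours, decay 0.8); PN, mu1, mu2 and lambda default to the
    midpoints of the recommended search grids (PN from 10-90%, mu from
    2^0..2^4, lambda from 2^-2..2^2 with lambda_m = lambda_d).
    """

    k_neighbors: int = 15
    alpha: float = 0.8
    wknnp_weight: str = "similarity"
    pn: float = 0.5
    mu1: float = 4.0
    mu2: float = 4.0
    ksns_tol: float = 1e-6
    ksns_max_iter: int = 500
    fusion_dim: int | None = None  # default min(100, N-1) per side
    restart_p: float = 0.5
    fusion_mode: str = "average"
    lambda_m: float = 1.0
    lambda_d: float = 1.0
    solver: str = "exact"  # "exact" (eigendecomposition) or "adagrad"
    propagate_on: str = "modified"  # "modified" (X-hat) or "raw" (binary X)
    eta0: float = 0.1
    solver_tol: float = 1e-6
    solver_max_iter: int = 1000

    def with_lambda(self, lam: float) -> "KNMBPParams":
        return replace(self, lambda_m=lam, lambda_d=lam)

    def propagation_params(self) -> PropagationParams:
        return PropagationParams(
            lambda_m=self.lambda_m,
            lambda_d=self.lambda_d,
            eta0=self.eta0,
            tol=self.solver_tol,
            max_iter=self.solver_max_iter,
        )


def disease_semantic_similarity(
    dag: DiseaseDAG,
    corpora: list[CorpusAnnotation],
    terms: list[str] | None = None,
    params: KNMBPParams | None = None,
) -> LabeledMatrix:
    """Per-corpus semantic similarity matrices fused into SS_d."""
    if params is None:
        params = KNMBPParams()
    per_corpus = semantic_similarity_matrix(dag, corpora, terms=terms)
    return fuse_similarity(
        per_corpus,
        dim=params.fusion_dim,
        restart_p=params.restart_p,
        mode=params.fusion_mode,
    )


def predict_scores(
    interactions: InteractionMatrix,
    sf_m: LabeledMatrix,
    ss_d: LabeledMatrix,
    params: KNMBPParams | None = None,
) -> InteractionMatrix:
    """Score every miRNA-disease pair from the observed interactions."""
    if params is None:
        params = KNMBPParams()
    sf_m = sf_m.reorder(interactions.row_labels)
    ss_d = ss_d.reorder(interactions.col_labels)
    xhat = modified_profile_matrix(
        interactions,
        sf_m,
        ss_d,
        k=params.k_neighbors,
        alpha=params.alpha,
        weight_mode=params.wknnp_weight,
    )
    si_m = kernel_neighborhood_similarity(
        xhat.values,
        sf_m,
        pn=params.pn,
        mu1=params.mu1,
        mu2=params.mu2,
        tol=params.ksns_tol,
        max_iter=params.ksns_max_iter,
    )
    si_d = kernel_neighborhood_similarity(
        xhat.values.T,
        ss_d,
        pn=params.pn,
        mu1=params.mu1,
        mu2=params.mu2,
        tol=params.ksns_tol,
        max_iter=params.ksns_max_iter,
    )
    s_m = fuse_similarity(
        [sf_m, LabeledMatrix(sf_m.labels, si_m)],
        dim=params.fusion_dim,
        restart_p=params.restart_p,
        mode=params.fusion_mode,
    )
    s_d = fuse_similarity(
        [ss_d, LabeledMatrix(ss_d.labels, si_d)],
        dim=params.fusion_dim,
        restart_p=params.restart_p,
        mode=params.fusion_mode,
    )
    lap_m = normalized_laplacian(s_m.values)
    lap_d = normalized_laplacian(s_d.values)
    y = xhat.values if params.propagate_on == "modified" else interactions.values
    prop = params.propagation_params()
    if params.solver == "exact":
        f = linear_solve(y, lap_m, lap_d, prop)
    elif params.solver == "adagrad":
        f = adagrad_solve(y, lap_m, lap_d, prop)
    else:
        raise ValueError(f"unknown solver {params.solver!r}")
    return interactions.with_values(f)


@dataclass
class CVReport:
    """Cross-validated performance of the pipeline for one CV mode."""

    mode: str
    seeds: list[int]
    per_seed: list[ROCResult]
    auc: float


def run_cv(
    interactions: InteractionMatrix,
    sf_m: LabeledMatrix,
    ss_d: LabeledMatrix,
    mode: str = "pairs",
    k: int = 5,
    seeds=(0, 1, 2, 3),
    params: KNMBPParams | None = None,
    n_thresholds: int = 1000,
) -> CVReport:
    """k-fold cross-validation of the full pipeline, averaged over seeds.

    For each fold the test pairs (or all pairs of the test rows/columns)
    are zeroed in the training matrix, the whole pipeline is recomputed on
    the training matrix alone, and the test entries are scored against the
    original labels.  Per-seed AUCs come from the fold-averaged threshold
    ROC; the reported AUC is their mean.
    """
    if params is None:
        params = KNMBPParams()
    y_true = interactions.values
    per_seed = []
    for seed in seeds:
        plan = cv_folds(interactions, mode, k=k, seed=seed)
        fold_scores, fold_labels = [], []
        for fold in range(plan.k):
            train_mask = plan.train_mask(fold)
            x_train = interactions.with_values(np.where(train_mask, y_true, 0.0))
            f = predict_scores(x_train, sf_m, ss_d, params)
            test = ~train_mask
            fold_scores.append(f.values[test])
            fold_labels.append(y_true[test])
        per_seed.append(roc_auc(fold_scores, fold_labels, n_thresholds=n_thresholds))
    return CVReport(mode, list(seeds), per_seed, mean_seed_auc(r.auc for r in per_seed))


def permuted_control(
    interactions: InteractionMatrix, seed: int = 0
) -> InteractionMatrix:
    """Shuffle all matrix entries, destroying any similarity-linked signal."""
    rng = np.random.default_rng(seed)
    flat = interactions.values.ravel().copy()
    rng.shuffle(flat)
    return interactions.with_values(flat.reshape(interactions.shape))
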