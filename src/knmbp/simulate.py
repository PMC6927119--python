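"""Synthetic study systems: DAG + corpora, gene network + targets, interactions.

The generator emulates the structure the method assumes in real data:

* a rooted disease DAG whose top-level branches act as disease families,
  with per-term annotation counts drawn from a zero-inflated Poisson
  (mimicking disease-gene / disease-GO corpora);
* a weighted gene network with modular structure (denser, stronger edges
  within gene modules, log-likelihood-style positive scores) and miRNA
  target sets drawn preferentially from one module;
* a binary interaction matrix sampled from low-rank probabilities built by
  smoothing Gaussian latent factors over the two similarity graphs, so that
  similar miRNAs (diseases) share interaction partners — the assumption the
  predictor exploits.  A fraction of sampled interactions is held out as
  evaluation positives, and annotation noise flips a fraction of the
  observed positives against random negatives.

Everything is deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import InteractionMatrix, LabeledMatrix
from .gene_network import GeneNetwork, mirna_functional_similarity, normalize_gene_network
from .ontology import CorpusAnnotation, DiseaseDAG


@dataclass
class FixtureConfig:
    """Sizes and sparsity of one synthetic study system."""

    n_diseases: int = 150
    n_mirnas: int = 200
    n_genes: int = 500
    dag_branching: float = 3.0  # mean children per internal term
    corpus_density: float = 0.75  # fraction of terms with nonzero counts
    network_density: float = 0.05  # overall gene-edge density
    target_set_size: int = 10  # mean targets per miRNA
    latent_rank: int = 5  # rank of the planted interaction structure
    interaction_density: float = 0.04  # expected fraction of 1-entries
    holdout_fraction: float = 0.1  # sampled positives held out for evaluation
    noise: float = 0.05  # fraction of observed positives flipped
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_mirnas, self.n_genes) < 2:
            raise ValueError("all sizes must be >= 2")
        if not 0 < self.network_density <= 1 or not 0 < self.corpus_density <= 1:
            raise ValueError("densities must be in (0, 1]")
        if self.latent_rank > min(self.n_mirnas, self.n_diseases):
            raise ValueError("latent rank exceeds matrix dimensions")


def _term_groups(config: FixtureConfig) -> np.ndarray:
    """Disease family assignment: term i belongs to branch i mod rank."""
    return np.arange(config.n_diseases) % config.latent_rank


def generate_dag(
    config: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[DiseaseDAG, list[CorpusAnnotation]]:
    """Random rooted DAG of disease terms plus two annotation corpora.

    The root has one child per disease family; every further term attaches
    to one or two earlier terms of its own family, so families form DAG
    branches and within-family pairs share deep ancestors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root = "ROOT"
    terms = [f"D{i:04d}" for i in range(config.n_diseases)]
    n_fam = min(config.latent_rank, config.n_diseases)
    groups = _term_groups(config)
    edges: set[tuple[str, str]] = set()
    members: dict[int, list[int]] = {g: [] for g in range(n_fam)}
    for i, term in enumerate(terms):
        fam = int(groups[i])
        pool = members[fam]
        if not pool:
            edges.add((term, root))
        else:
            n_par = 1 if len(pool) == 1 or rng.random() < 1.0 / config.dag_branching else 2
            for p in rng.choice(len(pool), size=n_par, replace=False):
                edges.add((term, terms[pool[p]]))
        members[fam].append(i)
    dag = DiseaseDAG([root] + terms, edges, root)
    corpora = []
    for cid, lam in (("D-G", 8.0), ("D-GO", 5.0)):
        nonzero = rng.random(config.n_diseases) < config.corpus_density
        counts = rng.poisson(lam, size=config.n_diseases)
        counts = np.where(nonzero, np.maximum(counts, 1), 0)
        corpora.append(
            CorpusAnnotation(cid, {t: int(c) for t, c in zip(terms, counts) if c > 0})
        )
    return dag, corpora


def generate_gene_side(
    config: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[GeneNetwork, dict[str, set]]:
    """Modular weighted gene network plus miRNA target sets.

    Genes split into ``latent_rank`` modules; within-module edges are denser
    and carry higher log-likelihood scores.  Each miRNA belongs to one
    module and draws ~80% of its targets from that module's genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    modules = np.arange(config.n_genes) % config.latent_rank
    p_out = config.network_density / 2.0
    p_in = min(1.0, config.network_density * 8.0)
    same = modules[:, None] == modules[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((config.n_genes, config.n_genes)) < prob, k=1)
    ii, jj = np.nonzero(upper)
    scores = np.where(
        modules[ii] == modules[jj],
        rng.uniform(1.5, 4.0, size=ii.size),
        rng.uniform(0.2, 2.0, size=ii.size),
    )
    edges = [(genes[a], genes[b], float(s)) for a, b, s in zip(ii, jj, scores)]
    net = normalize_gene_network(edges, genes=genes)
    gene_by_module = {m: np.flatnonzero(modules == m) for m in range(config.latent_rank)}
    targets: dict[str, set] = {}
    for i in range(config.n_mirnas):
        mod = i % config.latent_rank
        size = max(1, int(rng.poisson(config.target_set_size)))
        own = gene_by_module[mod]
        picks = []
        for _ in range(size):
            if rng.random() < 0.8:
                picks.append(int(rng.choice(own)))
            else:
                picks.append(int(rng.integers(config.n_genes)))
        targets[f"mir{i:04d}"] = {genes[g] for g in picks}
    return net, targets


def _smooth(similarity: np.ndarray, factors: np.ndarray, steps: int = 2) -> np.ndarray:
    rows = similarity.sum(axis=1, keepdims=True)
    p = similarity / np.where(rows > 0, rows, 1.0)
    out = factors
    for _ in range(steps):
        out = p @ out
    return out


@dataclass
class PlantedInteractions:
    """Observed matrix plus the evaluation positives hidden from it."""

    observed: InteractionMatrix
    held_out: list[tuple[str, str]]
    probabilities: np.ndarray


def generate_interactions(
    config: FixtureConfig,
    sf_m: LabeledMatrix,
    ss_d: LabeledMatrix,
    rng: np.random.Generator | None = None,
) -> PlantedInteractions:
    """Sample a binary interaction matrix with graph-smoothed low-rank signal.

    Gaussian latent factors are smoothed over the miRNA and disease
    similarity graphs, their inner products are squashed into Bernoulli
    probabilities calibrated to ``interaction_density``, the matrix is
    sampled, ``holdout_fraction`` of sampled positives is removed as
    held-out truth, and ``noise`` flips observed positives against random
    negatives last.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    nm, nd = sf_m.n, ss_d.n
    a = _smooth(sf_m.values, rng.standard_normal((nm, config.latent_rank)))
    b = _smooth(ss_d.values, rng.standard_normal((nd, config.latent_rank)))
    z = a @ b.T
    z = (z - z.mean()) / max(z.std(), 1e-12)
    cut = np.quantile(z, 1.0 - config.interaction_density)
    prob = 1.0 / (1.0 + np.exp(-(z - cut) / 0.25))
    y = (rng.random((nm, nd)) < prob).astype(float)
    ones = np.flatnonzero(y.ravel() == 1)
    rng.shuffle(ones)
    n_hold = int(round(config.holdout_fraction * ones.size))
    held_idx = ones[:n_hold]
    y.flat[held_idx] = 0.0
    observed_ones = ones[n_hold:]
    n_flip = int(round(config.noise * observed_ones.size))
    if n_flip:
        drop = rng.choice(observed_ones, size=n_flip, replace=False)
        y.flat[drop] = 0.0
        forbidden = set(held_idx.tolist()) | set(observed_ones.tolist())
        zeros = np.array(
            [i for i in np.flatnonzero(y.ravel() == 0) if i not in forbidden]
        )
        add = rng.choice(zeros, size=n_flip, replace=False)
        y.flat[add] = 1.0
    observed = InteractionMatrix(sf_m.labels, ss_d.labels, y)
    held_out = [
        (sf_m.labels[i // nd], ss_d.labels[i % nd]) for i in np.sort(held_idx)
    ]
    return PlantedInteractions(observed, held_out, prob)


@dataclass
class FixtureBundle:
    """Everything one end-to-end run needs, generated from a single seed."""

    config: FixtureConfig
    dag: DiseaseDAG
    corpora: list[CorpusAnnotation]
    gene_network: GeneNetwork
    targets: dict[str, set]
    sf_m: LabeledMatrix
    interactions: InteractionMatrix
    held_out: list[tuple[str, str]]
    probabilities: np.ndarray
    ss_d: LabeledMatrix = None  # fused disease semantic similarity


def generate_bundle(config: FixtureConfig | None = None) -> FixtureBundle:
    """Generate the full input bundle (DAG, corpora, gene side, interactions)."""
    from .pipeline import disease_semantic_similarity

    if config is None:
        config = FixtureConfig()
    dag, corpora = generate_dag(config)
    net, targets = generate_gene_side(config)
    sf_m = mirna_functional_similarity(targets, net)
    ss_d = disease_semantic_similarity(dag, corpora)
    planted = generate_interactions(config, sf_m, ss_d)
    return FixtureBundle(
        config,
        dag,
        corpora,
        net,
        targets,
        sf_m,
        planted.observed,
        planted.held_out,
        planted.probabilities,
        ss_d,
    )
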