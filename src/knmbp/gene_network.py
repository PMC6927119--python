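"""miRNA functional similarity from a weighted gene network and target sets.

Log-likelihood scores (LLS) between genes, as distributed by functional gene
networks such as HumanNet, are normalized by the maximum score to give a
gene-gene similarity in [0, 1].  The similarity of a gene to a gene set is
the best match inside the set, and two miRNAs are compared by the average
best-match similarity of their target sets in both directions:

    S^g(gi, gj) = LLS(i, j) / MAX_LLS            (0 when unlinked)
    S^g(g, G)   = max over gj in G of S^g(g, gj) (1 when g is in G)
    SF(mi, mj)  = ( sum_{g in Gi} S^g(g, Gj) + sum_{g in Gj} S^g(g, Gi) )
                  / (|Gi| + |Gj|)

This uses no miRNA-disease information, so the resulting similarity is
defined for miRNAs with no known disease association.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import LabeledMatrix
from .errors import InvalidNetworkError


@dataclass
class GeneNetwork:
    """Normalized symmetric gene-gene similarity with unit self-similarity."""

    genes: list[str]
    values: np.ndarray  # dense symmetric matrix in [0, 1], diag 1
    max_lls: float

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def similarity(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.values[ia, ib])

    def index_of(self, gene: str) -> int | None:
        return self._index.get(gene)


def normalize_gene_network(
    edges, max_lls: float | None = None, genes: list[str] | None = None
) -> GeneNetwork:
    """Normalize an LLS edge list into a symmetric [0, 1] similarity.

    ``edges`` is an iterable of (gene_a, gene_b, score).  Negative scores are
    clamped to 0 before normalization.  If both orientations of a pair are
    present the larger score wins.  Self-similarity is set to 1.
    """
    edges = [(str(a), str(b), float(s)) for a, b, s in edges]
    if genes is None:
        genes = sorted({g for a, b, _ in edges for g in (a, b)})
    if max_lls is None:
        max_lls = max((s for _, _, s in edges), default=0.0)
    if max_lls <= 0:
        raise InvalidNetworkError(f"maximum log-likelihood score must be > 0, got {max_lls}")
    index = {g: i for i, g in enumerate(genes)}
    vals = np.zeros((len(genes), len(genes)))
    for a, b, s in edges:
        if a == b:
            continue
        s = max(s, 0.0) / max_lls
        ia, ib = index[a], index[b]
        if s > vals[ia, ib]:
            vals[ia, ib] = vals[ib, ia] = s
    np.clip(vals, 0.0, 1.0, out=vals)
    np.fill_diagonal(vals, 1.0)
    return GeneNetwork(genes, vals, max_lls)


def gene_set_similarity(gene: str, gene_set, net: GeneNetwork) -> float:
    """Best-match similarity of one gene to a nonempty gene set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set must be nonempty")
    if gene in gene_set:
        return 1.0
    return max(net.similarity(gene, g) for g in gene_set)


def mirna_functional_similarity(targets: dict[str, set], net: GeneNetwork) -> LabeledMatrix:
    """Functional similarity matrix over miRNAs from their target gene sets.

    miRNAs with an empty target set are excluded with a warning: the measure
    is undefined for them.  The result is symmetric with unit diagonal and
    entries in [0, 1].
    """
    empty = sorted(m for m, g in targets.items() if not g)
    if empty:
        warnings.warn(f"excluding {len(empty)} miRNA(s) with empty target sets: {empty}")
    mirnas = sorted(m for m, g in targets.items() if g)
    # best-match of every gene in the network against each target set,
    # computed columnwise so the pair loop is a couple of gathers
    n_genes = len(net.genes)
    sets = []
    best = np.zeros((len(mirnas), n_genes))
    for i, m in enumerate(mirnas):
        idx = np.array(
            sorted(j for j in (net.index_of(g) for g in targets[m]) if j is not None),
            dtype=int,
        )
        sets.append(idx)
        if idx.size:
            best[i] = net.values[:, idx].max(axis=1)
    in_net_sizes = np.array([idx.size for idx in sets])
    full_sizes = np.array([len(targets[m]) for m in mirnas])
    mat = np.zeros((len(mirnas), len(mirnas)))
    for i in range(len(mirnas)):
        gi = sets[i]
        for j in range(i + 1, len(mirnas)):
            gj = sets[j]
            # genes absent from the network contribute 0 to the sums but
            # still count in the set sizes
            s = best[j][gi].sum() + best[i][gj].sum() if gi.size and gj.size else 0.0
            mat[i, j] = mat[j, i] = s / (full_sizes[i] + full_sizes[j])
    np.fill_diagonal(mat, 1.0)
    np.clip(mat, 0.0, 1.0, out=mat)
    return LabeledMatrix(mirnas, mat)
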