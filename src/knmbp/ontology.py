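"""Disease semantic similarity from an ontology DAG and annotation corpora.

A disease vocabulary (MeSH-style) is a rooted directed acyclic graph.  Each
disease term accumulates the annotation frequency of itself and all of its
descendants; the normalized frequency plays the role of an information
content, and the similarity of two terms is scored through their most
specific common ancestors:

    FT(d) = f(d) + sum over direct children c of FT(c)
    PT(d) = FT(d) / FT(root)
    S(d1, d2) = max over a in COM(d1, d2) of
                2 log PT(a) / (log PT(d1) + log PT(d2))

where COM(d1, d2) is the set of common ancestors (a term counts as its own
ancestor) with no descendant that is also a common ancestor.  One similarity
matrix is produced per annotation corpus (e.g. disease-gene and
disease-GO-process edge sets).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import LabeledMatrix
from .errors import CycleError, DegenerateCorpusError

VIRTUAL_ROOT = "ROOT*"


@dataclass
class DiseaseDAG:
    """Rooted DAG of disease terms; edges point from child to parent."""

    terms: list[str]
    parent_edges: set[tuple[str, str]]
    root: str

    def __post_init__(self) -> None:
        self.terms = list(self.terms)
        self.parent_edges = {tuple(e) for e in self.parent_edges}
        known = set(self.terms)
        if self.root not in known:
            raise ValueError(f"root {self.root!r} is not among the terms")
        for child, parent in self.parent_edges:
            if child == parent:
                raise ValueError(f"self-loop on term {child!r}")
            if child not in known or parent not in known:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
        # child -> parent digraph; ancestors are reachable sets
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        try:
            self._order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cyc = nx.find_cycle(g)
            raise CycleError(tuple(cyc[0][:2])) from None
        for t in self.terms:
            if t != self.root and self.root not in nx.descendants(g, t):
                raise ValueError(f"term {t!r} does not reach the root {self.root!r}")
        self._graph = g

    @classmethod
    def from_edges(cls, edges, extra_terms=()) -> "DiseaseDAG":
        """Build from (child, parent) pairs; inserts a virtual root if needed.

        If more than one maximal (parentless) term exists, a single term
        ``ROOT*`` is added as their common parent so that frequency
        normalization has a unique root.
        """
        edges = {(str(c), str(p)) for c, p in edges}
        terms = sorted({t for e in edges for t in e} | {str(t) for t in extra_terms})
        with_parent = {c for c, _ in edges}
        maximal = [t for t in terms if t not in with_parent]
        if not maximal:
            raise CycleError(next(iter(edges)))
        if len(maximal) == 1:
            root = maximal[0]
        else:
            root = VIRTUAL_ROOT
            if root in terms:
                raise ValueError(f"reserved term name {root!r} present in input")
            terms.append(root)
            edges |= {(t, root) for t in maximal}
        return cls(terms, edges, root)

    def children(self, term: str) -> list[str]:
        """Direct children of a term (its in-neighbours in the child->parent graph)."""
        return sorted(self._graph.predecessors(term))

    def parents(self, term: str) -> list[str]:
        return sorted(self._graph.successors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        anc = nx.descendants(self._graph, term)
        if include_self:
            anc = anc | {term}
        return anc

    def descendants(self, term: str, include_self: bool = False) -> set[str]:
        dec = nx.ancestors(self._graph, term)
        if include_self:
            dec = dec | {term}
        return dec

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        return list(self._order)


@dataclass
class CorpusAnnotation:
    """Per-term annotation counts from one corpus (disease-gene, disease-GO...)."""

    corpus_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative annotation counts: {bad}")

    def count(self, term: str) -> int:
        return int(self.counts.get(term, 0))


def propagate_frequency(
    dag: DiseaseDAG, ann: CorpusAnnotation, mode: str = "sum"
) -> dict[str, float]:
    """Accumulate corpus frequencies up the DAG.

    ``mode='sum'`` recurses over direct children, so a multi-parent term
    contributes once per parent lineage.  ``mode='union'`` counts every
    annotated descendant exactly once (FT(d) = sum of f over the descendant
    closure of d).
    """
    if mode not in ("sum", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    ft: dict[str, float] = {}
    if mode == "sum":
        for term in dag.topological_order():
            ft[term] = float(ann.count(term)) + sum(ft[c] for c in dag.children(term))
    else:
        for term in dag.terms:
            closure = dag.descendants(term, include_self=True)
            ft[term] = float(sum(ann.count(t) for t in closure))
    return ft


def normalize_frequency(ft: dict[str, float], dag: DiseaseDAG) -> dict[str, float]:
    """Normalize accumulated frequencies by the root's, giving PT in [0, 1]."""
    ft_root = ft[dag.root]
    if ft_root <= 0:
        raise DegenerateCorpusError(
            f"root frequency is {ft_root}; corpus carries no annotations"
        )
    return {t: ft[t] / ft_root for t in dag.terms}


def most_specific_common_ancestors(dag: DiseaseDAG, d1: str, d2: str) -> set[str]:
    """Common ancestors of d1 and d2 (terms included) with no common-ancestor descendant."""
    common = dag.ancestors(d1) & dag.ancestors(d2)
    out = set()
    for a in common:
        if not (dag.descendants(a) & common):
            out.add(a)
    return out


def semantic_similarity_pair(
    pt: dict[str, float], dag: DiseaseDAG, d1: str, d2: str
) -> float:
    """Similarity of two terms through their most specific common ancestors.

    Terms with PT = 0 carry no information and score 0 against everything;
    a common ancestor with PT = 1 (the root) contributes 0 (log 1 = 0).
    """
    if d1 not in pt or d2 not in pt:
        missing = d1 if d1 not in pt else d2
        raise KeyError(f"unknown term {missing!r}")
    p1, p2 = pt[d1], pt[d2]
    if p1 <= 0 or p2 <= 0:
        return 0.0
    denom = math.log(p1) + math.log(p2)
    if denom == 0.0:
        # both terms sit at the root: no information to share
        return 0.0
    best = 0.0
    for a in most_specific_common_ancestors(dag, d1, d2):
        pa = pt[a]
        if pa <= 0:
            continue
        best = max(best, 2.0 * math.log(pa) / denom)
    return best


def semantic_similarity_matrix(
    dag: DiseaseDAG,
    corpora: list[CorpusAnnotation],
    terms: list[str] | None = None,
    mode: str = "sum",
) -> list[LabeledMatrix]:
    """One semantic similarity matrix per corpus over ``terms`` (default: all).

    Each matrix is symmetric with entries in [0, 1]; the diagonal is 1 for
    every term with 0 < PT < 1.
    """
    if not corpora:
        raise ValueError("at least one corpus is required")
    if terms is None:
        terms = [t for t in dag.terms if t != dag.root]
    n = len(terms)
    # precompute inclusive ancestor sets once; shared across corpora
    anc = {t: dag.ancestors(t) for t in terms}
    desc = {}
    out = []
    for corpus in corpora:
        pt = normalize_frequency(propagate_frequency(dag, corpus, mode=mode), dag)
        logpt = {t: (math.log(p) if p > 0 else None) for t, p in pt.items()}
        mat = np.zeros((n, n))
        for i, d1 in enumerate(terms):
            if logpt[d1] is None:
                continue
            for j in range(i, n):
                d2 = terms[j]
                if logpt[d2] is None:
                    continue
                denom = logpt[d1] + logpt[d2]
                if denom == 0.0:
                    continue
                common = anc[d1] & anc[d2]
                best = 0.0
                for a in common:
                    la = logpt[a]
                    if la is None:
                        continue
                    if a not in desc:
                        desc[a] = dag.descendants(a)
                    if desc[a] & common:
                        continue  # a more specific common ancestor exists
                    best = max(best, 2.0 * la / denom)
                mat[i, j] = mat[j, i] = best
        out.append(LabeledMatrix(terms, mat))
    return out
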