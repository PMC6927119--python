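"""Delimited-text readers/writers and label-universe reconciliation.

All inputs are plain delimited text (tab or comma, sniffed), with optional
headers and ``#`` comment lines:

* ontology: two columns (child_id, parent_id);
* corpus: two columns (disease_id, object_id) — f(d) is the row count per
  disease;
* gene network: three columns (gene_a, gene_b, score);
* targets: two columns (mirna_id, gene_id);
* interactions: two columns (mirna_id, disease_id), one row per known pair.

Outputs (matrices, score tables, ranked candidate lists, CV reports) are
tab-separated with a header comment recording the seed and a hash of the
configuration that produced them.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import InteractionMatrix, LabeledMatrix
from .gene_network import GeneNetwork, normalize_gene_network
from .ontology import CorpusAnnotation, DiseaseDAG

logger = logging.getLogger("knmbp")

_HEADER_WORDS = {
    "child", "parent", "child_id", "parent_id", "term", "disease", "disease_id",
    "mirna", "mirna_id", "gene", "gene_id", "gene_a", "gene_b", "object",
    "object_id", "go", "go_id", "score", "lls", "target", "target_id", "weight",
}


def _read_table(path, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=None, engine="python", comment="#", header=None, dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected {n_cols} columns, found {df.shape[1]}")
    df = df.iloc[:, :n_cols]
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if all(v in _HEADER_WORDS for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    bad = df.isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed line(s) at row(s) {list(df.index[bad])}")
    return df.apply(lambda c: c.str.strip())


def read_ontology(path) -> DiseaseDAG:
    """Read a (child, parent) edge table into a rooted DAG."""
    df = _read_table(path, 2)
    return DiseaseDAG.from_edges(df.itertuples(index=False, name=None))


def read_corpus(path, corpus_id: str | None = None) -> CorpusAnnotation:
    """Read a (disease, object) edge table; counts are rows per disease."""
    df = _read_table(path, 2)
    counts = df.iloc[:, 0].value_counts().to_dict()
    return CorpusAnnotation(corpus_id or Path(path).stem, {k: int(v) for k, v in counts.items()})


def read_gene_network(path, max_lls: float | None = None) -> GeneNetwork:
    """Read a (gene_a, gene_b, score) edge table into a normalized network."""
    df = _read_table(path, 3)
    edges = [(a, b, float(s)) for a, b, s in df.itertuples(index=False, name=None)]
    return normalize_gene_network(edges, max_lls=max_lls)


def read_targets(path) -> dict[str, set]:
    """Read a (mirna, gene) edge table into target sets."""
    df = _read_table(path, 2)
    targets: dict[str, set] = {}
    for m, g in df.itertuples(index=False, name=None):
        targets.setdefault(m, set()).add(g)
    return targets


def read_interactions(
    path, mirnas: list[str], diseases: list[str]
) -> InteractionMatrix:
    """Read known (mirna, disease) pairs into a binary matrix over given labels.

    Pairs whose miRNA or disease has no computable similarity (absent from
    the label universes) are dropped and counted in the log; duplicates
    collapse to a single 1-entry.
    """
    df = _read_table(path, 2)
    ri = {m: i for i, m in enumerate(mirnas)}
    ci = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)))
    dropped = 0
    for m, d in df.itertuples(index=False, name=None):
        i, j = ri.get(m), ci.get(d)
        if i is None or j is None:
            dropped += 1
            continue
        values[i, j] = 1.0
    kept = int(values.sum())
    logger.info(
        "interactions: %d unique pairs kept, %d rows dropped (unknown entities)",
        kept, dropped,
    )
    if kept == 0:
        raise ValueError(
            f"{path}: no interaction involves a known miRNA and disease "
            f"({dropped} rows dropped)"
        )
    return InteractionMatrix(mirnas, diseases, values)


def config_hash(config) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config, seed) -> str:
    return f"# knmbp config_hash={config_hash(config)} seed={seed}\n"


def write_matrix(path, matrix, config=None, seed=None) -> None:
    """Write a labelled matrix as TSV with a provenance header comment."""
    frame = matrix.to_frame()
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config, seed))
        frame.to_csv(fh, sep="\t")


def write_scores(path, scores: InteractionMatrix, config=None, seed=None) -> None:
    """Write one (mirna, disease, score) row per pair, descending by score."""
    rows = scores.to_frame().stack().rename("score").reset_index()
    rows.columns = ["mirna_id", "disease_id", "score"]
    rows = rows.sort_values("score", ascending=False, kind="stable")
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config, seed))
        rows.to_csv(fh, sep="\t", index=False)


def write_ranked_candidates(
    path, scores: InteractionMatrix, known: InteractionMatrix | None = None,
    config=None, seed=None,
) -> None:
    """Per-disease candidate miRNAs ranked by score (known pairs flagged)."""
    frames = []
    for j, disease in enumerate(scores.col_labels):
        order = np.argsort(-scores.values[:, j], kind="stable")
        frame = pd.DataFrame(
            {
                "disease_id": disease,
                "rank": np.arange(1, len(order) + 1),
                "mirna_id": [scores.row_labels[i] for i in order],
                "score": scores.values[order, j],
            }
        )
        if known is not None:
            frame["known"] = known.values[order, j].astype(int)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config, seed))
        out.to_csv(fh, sep="\t", index=False)


def write_cv_report(path, report, config=None, seed=None) -> None:
    """Mean TPR/FPR per threshold plus per-seed and final AUC."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config, seed))
        fh.write(f"# mode={report.mode} auc={report.auc:.6f}\n")
        for s, res in zip(report.seeds, report.per_seed):
            fh.write(f"# seed={s} auc={res.auc:.6f}\n")
        first = report.per_seed[0]
        mean_tpr = np.mean([r.mean_tpr for r in report.per_seed], axis=0)
        mean_fpr = np.mean([r.mean_fpr for r in report.per_seed], axis=0)
        pd.DataFrame(
            {"threshold": first.thresholds, "mean_tpr": mean_tpr, "mean_fpr": mean_fpr}
        ).to_csv(fh, sep="\t", index=False)


def write_bundle(outdir, bundle) -> dict[str, Path]:
    """Dump a synthetic bundle in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = paths["ontology"] = outdir / "ontology.tsv"
    with open(p, "w") as fh:
        fh.write("# child_id\tparent_id\n")
        for child, parent in sorted(bundle.dag.parent_edges):
            fh.write(f"{child}\t{parent}\n")
    for corpus in bundle.corpora:
        p = paths[f"corpus_{corpus.corpus_id}"] = outdir / f"corpus_{corpus.corpus_id}.tsv"
        with open(p, "w") as fh:
            fh.write("# disease_id\tobject_id\n")
            for term in sorted(corpus.counts):
                for k in range(corpus.counts[term]):
                    fh.write(f"{term}\t{corpus.corpus_id}_obj{k:05d}\n")
    p = paths["gene_network"] = outdir / "gene_network.tsv"
    net = bundle.gene_network
    with open(p, "w") as fh:
        fh.write("# gene_a\tgene_b\tscore\n")
        n = len(net.genes)
        for i in range(n):
            for j in range(i + 1, n):
                if net.values[i, j] > 0:
                    fh.write(
                        f"{net.genes[i]}\t{net.genes[j]}\t{net.values[i, j] * net.max_lls:.6f}\n"
                    )
    p = paths["targets"] = outdir / "targets.tsv"
    with open(p, "w") as fh:
        fh.write("# mirna_id\tgene_id\n")
        for m in sorted(bundle.targets):
            for g in sorted(bundle.targets[m]):
                fh.write(f"{m}\t{g}\n")
    p = paths["interactions"] = outdir / "interactions.tsv"
    with open(p, "w") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        ii, jj = np.nonzero(bundle.interactions.values)
        for i, j in zip(ii, jj):
            fh.write(
                f"{bundle.interactions.row_labels[i]}\t{bundle.interactions.col_labels[j]}\n"
            )
    return paths
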