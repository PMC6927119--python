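"""Labelled matrix containers shared by every pipeline stage.

Two shapes recur throughout the method: square similarity matrices over one
entity set (diseases, miRNAs or genes) and the rectangular miRNA x disease
interaction/score matrices.  Both carry their labels so that stages can
reconcile entity universes instead of trusting positional order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledMatrix:
    """Square matrix over one set of entities (similarity-matrix roles)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def reorder(self, labels: list[str]) -> "LabeledMatrix":
        idx = np.array([self._index[lab] for lab in labels])
        return LabeledMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class InteractionMatrix:
    """miRNA x disease matrix: binary interactions, modified profiles or scores.

    Rows are miRNAs, columns are diseases.  ``values`` is binary for the raw
    interaction matrix and real-valued for its weighted-neighbour correction
    and for predicted score matrices.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = list(self.row_labels)
        self.col_labels = list(self.col_labels)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match label counts")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("column labels must be unique")
        self._rindex = {lab: i for i, lab in enumerate(self.row_labels)}
        self._cindex = {lab: i for i, lab in enumerate(self.col_labels)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def loc(self, mirna: str, disease: str) -> float:
        return float(self.values[self._rindex[mirna], self._cindex[disease]])

    def with_values(self, values: np.ndarray) -> "InteractionMatrix":
        return InteractionMatrix(self.row_labels, self.col_labels, values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)
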