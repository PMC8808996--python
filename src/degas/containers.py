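"""Core in-memory containers for expression data and sample labels.

An :class:`ExpressionMatrix` is a samples x genes numeric matrix carrying
ordered sample and gene identifiers plus a ``stage`` tag recording which
normalisation steps have been applied (``raw`` counts/TPM -> ``log2`` ->
per-sample ``zscore`` -> per-sample ``unit`` [0,1] scaling).  The deep
learning model only accepts ``unit``-stage input.

A :class:`LabelSet` attaches either a one-hot class matrix or a
(time, event) survival table to the rows of a paired ExpressionMatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_STAGES = ("raw", "log2", "zscore", "unit")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {dups[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples x genes matrix")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.stage not in VALID_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {VALID_STAGES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/Inf")
        if self.stage == "unit":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("unit-stage values must lie in [0,1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.sample_ids), list(self.gene_ids),
                                stage if stage is not None else self.stage)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(self.sample_ids),
                                [str(g) for g in genes], self.stage)

    def subset_samples(self, rows: Sequence[int]) -> "ExpressionMatrix":
        rows = np.asarray(rows, dtype=int)
        return ExpressionMatrix(self.values[rows], [self.sample_ids[i] for i in rows],
                                list(self.gene_ids), self.stage)


@dataclass
class LabelSet:
    """One-hot class labels, a survival table, or no labels, for n samples."""

    kind: str = "none"  # class_onehot | survival | none
    onehot: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("class_onehot", "survival", "none"):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind == "class_onehot":
            self.onehot = np.asarray(self.onehot, dtype=np.float64)
            if self.onehot.ndim != 2:
                raise ValueError("onehot must be 2-d")
            if not np.all(np.isin(self.onehot, (0.0, 1.0))):
                raise ValueError("onehot entries must be 0/1")
            if not np.all(self.onehot.sum(axis=1) == 1):
                raise ValueError("every onehot row must sum to exactly 1")
            if not self.class_names:
                self.class_names = [f"class{j}" for j in range(self.onehot.shape[1])]
            if len(self.class_names) != self.onehot.shape[1]:
                raise ValueError("class_names length must match onehot columns")
        elif self.kind == "survival":
            self.time = np.asarray(self.time, dtype=np.float64)
            self.event = np.asarray(self.event, dtype=np.float64)
            if self.time.shape != self.event.shape or self.time.ndim != 1:
                raise ValueError("time and event must be equal-length vectors")
            if np.any(self.time <= 0):
                raise ValueError("survival times must be strictly positive")
            if not np.all(np.isin(self.event, (0.0, 1.0))):
                raise ValueError("event indicator must be 0 (censored) or 1 (event)")

    @property
    def n_samples(self) -> int:
        if self.kind == "class_onehot":
            return self.onehot.shape[0]
        if self.kind == "survival":
            return self.time.shape[0]
        return 0

    def labels(self) -> np.ndarray:
        """Class name per sample (class_onehot only)."""
        if self.kind != "class_onehot":
            raise ValueError("labels() requires class_onehot kind")
        return np.asarray(self.class_names, dtype=object)[np.argmax(self.onehot, axis=1)]

    def subset(self, rows: Sequence[int]) -> "LabelSet":
        rows = np.asarray(rows, dtype=int)
        if self.kind == "class_onehot":
            return LabelSet("class_onehot", onehot=self.onehot[rows],
                            class_names=list(self.class_names))
        if self.kind == "survival":
            return LabelSet("survival", time=self.time[rows], event=self.event[rows])
        return LabelSet("none")


def check_paired(X: ExpressionMatrix, y: LabelSet) -> None:
    if y.kind != "none" and y.n_samples != X.n_samples:
        raise ValueError(
            f"label rows ({y.n_samples}) do not match expression samples ({X.n_samples})"
        )


__all__ = ["ExpressionMatrix", "LabelSet", "check_paired", "VALID_STAGES", "replace"]
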