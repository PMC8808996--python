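"""Turning raw head outputs into interpretable association scores.

A head probability ``P`` over ``k`` labels is mapped to an association in
[-1, 1] via the affine transform ``2*((P - 1/k)/(2 - 2/k) + 1/2) - 1``,
algebraically ``(P - 1/k)/(1 - 1/k)``: 0 marks the no-association point
``P = 1/k`` and 1 maximal association.  For a sigmoid (Cox or binary)
output ``k = 2``, reducing the transform to ``2P - 1``.

kNN smoothing and mean-centering are small utilities used when
overlaying scores on a 2-d embedding; the embedding coordinates are
consumed, never computed, here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AssociationScores:
    values: np.ndarray  # vector or matrix in [-1, 1]
    k: int
    centered: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not self.centered and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("association scores must lie in [-1, 1]")


def to_corr_coeff(P: np.ndarray, k: int) -> AssociationScores:
    """Map head probabilities in [0,1] to associations in [-1,1].

    ``k`` is the number of labels the head distinguishes (2 for a
    sigmoid/Cox output).  Note the per-class minimum for ``k > 2`` is
    ``-1/(k-1)``, not -1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    P = np.asarray(P, float)
    if P.min() < -1e-12 or P.max() > 1 + 1e-12:
        raise ValueError("probabilities must lie in [0, 1]")
    assoc = 2.0 * ((P - 1.0 / k) / (2.0 - 2.0 / k) + 0.5) - 1.0
    return AssociationScores(assoc, k=k)


def from_corr_coeff(assoc: np.ndarray, k: int) -> np.ndarray:
    """Algebraic inverse of :func:`to_corr_coeff`."""
    assoc = np.asarray(assoc, float)
    return assoc * (1.0 - 1.0 / k) + 1.0 / k


def knn_smooth(values: np.ndarray, coords: np.ndarray, k_neighbors: int = 5) -> np.ndarray:
    """Average each value with its ``k_neighbors`` Euclidean nearest
    neighbors in the embedding (self included, so k+1 values per mean).

    Distance ties are broken by index order, making the result
    deterministic even with duplicate coordinates.
    """
    values = np.asarray(values, float).reshape(-1)
    coords = np.asarray(coords, float)
    n = values.shape[0]
    if coords.shape[0] != n:
        raise ValueError("coords rows must match values length")
    if not 0 < k_neighbors < n:
        raise ValueError("k_neighbors must be in [1, n-1]")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    # stable argsort => ties broken by index
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    return (values + values[nn].sum(axis=1)) / (k_neighbors + 1)


def center_func(values: np.ndarray) -> np.ndarray:
    """Subtract the mean so the output mean is 0 (idempotent)."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cannot center an empty vector")
    return values - values.mean(axis=0, keepdims=values.ndim > 1)


def write_scores_tsv(
    path: str | Path,
    sample_ids: list[str],
    raw: np.ndarray,
    association: np.ndarray,
    centered: np.ndarray | None = None,
    smoothed: np.ndarray | None = None,
) -> None:
    cols = {"raw_output": np.asarray(raw, float).reshape(-1),
            "association": np.asarray(association, float).reshape(-1)}
    if centered is not None:
        cols["association_centered"] = np.asarray(centered, float).reshape(-1)
    if smoothed is not None:
        cols["association_smoothed"] = np.asarray(smoothed, float).reshape(-1)
    pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id")).to_csv(path, sep="\t")


__all__ = ["AssociationScores", "to_corr_coeff", "from_corr_coeff",
           "knn_smooth", "center_func", "write_scores_tsv"]
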