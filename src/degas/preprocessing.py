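"""Feature selection and scaling of expression matrices.

The model consumes per-sample [0,1]-scaled z-scores of (optionally
log-transformed) expression, restricted to the gene set shared by the
single-cell and bulk matrices.  The canonical pipeline is::

    log2_transform -> sample_zscore -> unit_scale

applied after gene filtering and :func:`intersect_features`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, LabelSet


def log2_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of raw nonnegative expression.

    The +1 pseudocount maps the ubiquitous zero counts to zero.
    """
    if X.stage != "raw":
        raise ValueError(f"log2_transform expects raw stage, got {X.stage!r}")
    if X.values.min() < 0:
        i, j = np.unravel_index(np.argmin(X.values), X.values.shape)
        raise ValueError(
            f"negative expression value at sample {X.sample_ids[i]!r}, gene {X.gene_ids[j]!r}"
        )
    return X.with_values(np.log2(X.values + 1.0), stage="log2")


def sample_zscore(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample (row-wise) z-scores across genes.

    Uses the n-1 (sample) standard deviation; constant rows map to zeros.
    """
    if X.stage not in ("raw", "log2"):
        raise ValueError(f"sample_zscore expects raw or log2 stage, got {X.stage!r}")
    if X.n_genes < 2:
        raise ValueError("z-score across genes is degenerate with a single gene")
    mu = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=1, keepdims=True)
    out = np.divide(X.values - mu, sd, out=np.zeros_like(X.values), where=sd > 0)
    return X.with_values(out, stage="zscore")


def unit_scale(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample linear rescale to [0,1]; constant rows map to 0.5."""
    if X.stage != "zscore":
        raise ValueError(f"unit_scale expects zscore stage, got {X.stage!r}")
    lo = X.values.min(axis=1, keepdims=True)
    hi = X.values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.divide(X.values - lo, span, out=np.full_like(X.values, 0.5), where=span > 0)
    return X.with_values(out, stage="unit")


def scale_pipeline(X: ExpressionMatrix, log: bool = True) -> ExpressionMatrix:
    """The full log2 -> z-score -> [0,1] scaling pipeline."""
    if log:
        X = log2_transform(X)
    return unit_scale(sample_zscore(X))


def filter_by_variance(X: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Retain the top ``keep_fraction`` of genes by variance across samples.

    All genes tying the threshold variance are kept, so slightly more than
    ``keep_fraction * n_genes`` genes can be returned.  Gene order is
    preserved.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if X.n_samples < 2:
        raise ValueError("variance filter requires at least 2 samples")
    var = X.values.var(axis=0, ddof=1)
    n_keep = max(1, int(np.ceil(keep_fraction * X.n_genes)))
    thresh = np.sort(var)[::-1][n_keep - 1]
    keep = var >= thresh
    if not keep.any():
        raise ValueError("variance filter removed every gene")
    genes = [g for g, k in zip(X.gene_ids, keep) if k]
    return X.subset_genes(genes)


def filter_by_nonzero(X: ExpressionMatrix, min_fraction: float) -> ExpressionMatrix:
    """Keep genes whose fraction of nonzero samples strictly exceeds ``min_fraction``."""
    if X.stage != "raw":
        raise ValueError("nonzero filter applies to raw counts")
    frac = (X.values != 0).mean(axis=0)
    keep = frac > min_fraction
    if not keep.any():
        raise ValueError("nonzero filter removed every gene")
    return X.subset_genes([g for g, k in zip(X.gene_ids, keep) if k])


def intersect_features(
    X_cell: ExpressionMatrix, X_pat: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in cell-matrix order."""
    pat_genes = set(X_pat.gene_ids)
    shared = [g for g in X_cell.gene_ids if g in pat_genes]
    if not shared:
        raise ValueError(
            f"no shared genes between cell matrix ({X_cell.n_genes} genes) "
            f"and patient matrix ({X_pat.n_genes} genes)"
        )
    return X_cell.subset_genes(shared), X_pat.subset_genes(shared)


def one_hot_encode(labels: Sequence[str], class_names: Sequence[str] | None = None) -> LabelSet:
    """One-hot encode string labels into a LabelSet.

    Column order follows ``class_names`` when given, else sorted unique labels.
    """
    labels = [str(l) for l in labels]
    if class_names is None:
        class_names = sorted(set(labels))
    class_names = [str(c) for c in class_names]
    index = {c: j for j, c in enumerate(class_names)}
    unseen = sorted({l for l in labels if l not in index})
    if unseen:
        raise ValueError(f"labels not in class_names: {unseen}")
    onehot = np.zeros((len(labels), len(class_names)))
    for i, l in enumerate(labels):
        onehot[i, index[l]] = 1.0
    return LabelSet("class_onehot", onehot=onehot, class_names=class_names)


__all__ = [
    "log2_transform",
    "sample_zscore",
    "unit_scale",
    "scale_pipeline",
    "filter_by_variance",
    "filter_by_nonzero",
    "intersect_features",
    "one_hot_encode",
]
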