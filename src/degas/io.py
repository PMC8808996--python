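"""Readers and writers for expression matrices and label tables.

Dense TSV/CSV: header row = gene ids, first column = sample ids.
MatrixMarket: an ``.mtx`` file plus sidecar text files of row and column
names; the common cells-as-columns dialect (genes x cells, as written by
droplet pipelines) is auto-detected from the sidecar lengths and can be
forced with ``cells_as_columns``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, LabelSet


def read_expression_tsv(path: str | Path, stage: str = "raw", sep: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index],
                            [str(c) for c in df.columns], stage=stage)


def write_expression_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_expression_mtx(
    mtx_path: str | Path,
    row_names: str | Path,
    col_names: str | Path,
    stage: str = "raw",
    cells_as_columns: bool | None = None,
) -> ExpressionMatrix:
    """Read an MTX matrix with sidecar row/column name files.

    ``row_names``/``col_names`` name the MTX rows and columns respectively.
    If ``cells_as_columns`` is None it is inferred: when the matrix shape
    only matches the sidecars after transposition, the file is treated as
    genes x cells and transposed to samples x genes.
    """
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    rows = [l.strip().split("\t")[0] for l in Path(row_names).read_text().splitlines() if l.strip()]
    cols = [l.strip().split("\t")[0] for l in Path(col_names).read_text().splitlines() if l.strip()]
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars ({len(rows)} x {len(cols)})"
        )
    if cells_as_columns is None:
        # Heuristic: droplet matrices are genes x cells with far more
        # columns than rows and gene-like row names.
        cells_as_columns = mat.shape[1] > mat.shape[0]
    if cells_as_columns:
        return ExpressionMatrix(mat.T, cols, rows, stage=stage)
    return ExpressionMatrix(mat, rows, cols, stage=stage)


def read_labels_tsv(path: str | Path) -> LabelSet:
    """Read a label table: either survival columns (time, event) or a
    one-hot class matrix / single ``label`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [c.lower() for c in df.columns]
    if "time" in cols and "event" in cols:
        return LabelSet("survival",
                        time=df[df.columns[cols.index("time")]].to_numpy(float),
                        event=df[df.columns[cols.index("event")]].to_numpy(float))
    if list(df.columns) == ["label"] or (df.shape[1] == 1 and df.dtypes.iloc[0] == object):
        from .preprocessing import one_hot_encode

        return one_hot_encode(df.iloc[:, 0].astype(str).tolist())
    return LabelSet("class_onehot", onehot=df.to_numpy(float),
                    class_names=[str(c) for c in df.columns])


def write_labels_tsv(y: LabelSet, path: str | Path, sample_ids: list[str] | None = None) -> None:
    if y.kind == "survival":
        df = pd.DataFrame({"time": y.time, "event": y.event.astype(int)})
    elif y.kind == "class_onehot":
        df = pd.DataFrame(y.onehot.astype(int), columns=y.class_names)
    else:
        raise ValueError("cannot write an empty LabelSet")
    if sample_ids is not None:
        df.index = pd.Index(sample_ids, name="sample_id")
    df.to_csv(path, sep="\t", index=sample_ids is not None, index_label="sample_id")


__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_mtx",
    "read_labels_tsv",
    "write_labels_tsv",
]
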