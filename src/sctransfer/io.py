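"""Reading and writing expression matrices and label vectors.

Supported on-disk formats
-------------------------
TSV / CSV
    First column gene id, first row cell ids; dense values.
MatrixMarket (``mtx``)
    Coordinate format, genes as rows, with ``genes.txt`` / ``cells.txt``
    sidecar files (one identifier per line) next to the matrix file.
Labels
    Two-column TSV ``cell_id <tab> integer label`` with no header.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in ("tsv", "txt", "tab"):
        return "tsv"
    if ext == "csv":
        return "csv"
    if ext == "mtx":
        return "mtx"
    raise DataValidationError(f"cannot infer matrix format from {path!r}")


def _sidecar_paths(path: str) -> tuple[str, str]:
    base = os.path.dirname(str(path))
    return os.path.join(base, "genes.txt"), os.path.join(base, "cells.txt")


def read_matrix(
    path,
    format: str | None = None,
    unit: str = "counts",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Matrix file.  For ``mtx``, sidecar ``genes.txt`` / ``cells.txt``
        files must sit in the same directory.
    format
        ``tsv``, ``csv`` or ``mtx``; inferred from the extension if omitted.
    unit
        Unit tag to attach (``counts``, ``tpm``, ``cpm``, ``rpkm``, ``log``).
    transpose
        Set if the file stores cells as rows.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in _SEPS:
        if os.path.getsize(path) == 0:
            raise DataValidationError(f"empty matrix file: {path}")
        try:
            df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
        except Exception as exc:  # pragma: no cover - message wrapper
            raise DataValidationError(f"cannot parse {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise DataValidationError(f"no data columns in {path}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if transpose:
            df = df.T
        return ExpressionMatrix.from_dataframe(df, unit=unit)
    if fmt == "mtx":
        genes_path, cells_path = _sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not os.path.exists(p):
                raise DataValidationError(f"missing sidecar file {p}")
        m = scipy.io.mmread(path)
        values = np.asarray(m.todense() if sp.issparse(m) else m, dtype=float)
        genes = _read_id_file(genes_path)
        cells = _read_id_file(cells_path)
        if transpose:
            values = values.T
            genes, cells = cells, genes
        return ExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells, unit=unit)
    raise DataValidationError(f"unknown format {fmt!r}")


def write_matrix(X: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a matrix as TSV/CSV (dense) or MatrixMarket with sidecars."""
    path = str(path)
    fmt = format or _infer_format(path)
    if fmt in _SEPS:
        X.to_dataframe().to_csv(path, sep=_SEPS[fmt])
        return
    if fmt == "mtx":
        coo = sp.coo_matrix(X.values)
        if np.allclose(X.values, np.round(X.values)):
            coo = coo.astype(int)
        scipy.io.mmwrite(path, coo)
        genes_path, cells_path = _sidecar_paths(path)
        _write_id_file(genes_path, X.gene_ids)
        _write_id_file(cells_path, X.cell_ids)
        return
    raise DataValidationError(f"unknown format {fmt!r}")


def _read_id_file(path: str) -> np.ndarray:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def _write_id_file(path: str, ids) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_labels(path, cell_ids=None) -> np.ndarray:
    """Read a two-column ``cell_id <tab> label`` TSV.

    When *cell_ids* is given the labels are reordered to match and every
    cell must be present.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        raise DataValidationError("duplicate cell ids in label file")
    if cell_ids is not None:
        wanted = [str(c) for c in cell_ids]
        table = dict(zip(df["cell_id"], df["label"]))
        missing = [c for c in wanted if c not in table]
        if missing:
            raise DataValidationError(f"labels missing for cells: {missing[:5]}...")
        y = np.asarray([table[c] for c in wanted])
    else:
        y = df["label"].to_numpy()
    return validate_labels(y)


def write_labels(path, cell_ids, y) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": np.asarray(y, dtype=int)}).to_csv(
        path, sep="\t", header=False, index=False
    )
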