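"""In-memory containers for expression data.

The central object is :class:`ExpressionMatrix`, a dense genes x cells
matrix with gene/cell identifiers and a unit tag.  Orientation follows the
convention of most clustering method descriptions (genes as rows); helpers
convert to and from the cells x genes orientation used by AnnData.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError

#: recognised expression units; "log" marks a matrix that has already been
#: log-transformed and must not be transformed again.
UNITS = ("counts", "tpm", "cpm", "rpkm", "log")


@dataclass
class ExpressionMatrix:
    """Dense nonnegative genes x cells expression matrix.

    Parameters
    ----------
    values
        Nonnegative array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique ordered identifiers for rows and columns.
    unit
        One of ``counts, tpm, cpm, rpkm, log``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        if self.unit not in UNITS:
            raise DataValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise DataValidationError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise DataValidationError(f"duplicate {name} ids")
        if not np.isfinite(self.values).all():
            raise DataValidationError("expression values contain NaN or infinity")
        if (self.values < 0).any():
            raise DataValidationError("expression values must be nonnegative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- subsetting -----------------------------------------------------
    def subset_genes(self, index) -> "ExpressionMatrix":
        """Return a copy restricted to the given gene (row) index."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index, :].copy(),
            gene_ids=self.gene_ids[index].copy(),
            cell_ids=self.cell_ids.copy(),
        )

    def subset_cells(self, index) -> "ExpressionMatrix":
        """Return a copy restricted to the given cell (column) index."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index].copy(),
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[index].copy(),
        )

    # -- conversions ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Genes x cells DataFrame with gene ids as index, cell ids as columns."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, unit: str = "counts") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=df.index.to_numpy(dtype=object),
            cell_ids=df.columns.to_numpy(dtype=object),
            unit=unit,
        )

    def to_anndata(self):
        """Convert to an AnnData (cells x genes) object."""
        import anndata

        adata = anndata.AnnData(X=self.values.T.copy())
        adata.obs_names = [str(c) for c in self.cell_ids]
        adata.var_names = [str(g) for g in self.gene_ids]
        adata.uns["unit"] = self.unit
        return adata

    @classmethod
    def from_anndata(cls, adata, unit: str | None = None) -> "ExpressionMatrix":
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        return cls(
            values=np.asarray(X).T,
            gene_ids=adata.var_names.to_numpy(dtype=object),
            cell_ids=adata.obs_names.to_numpy(dtype=object),
            unit=unit or adata.uns.get("unit", "counts"),
        )


def validate_labels(y, n_cells: int | None = None, k: int | None = None) -> np.ndarray:
    """Coerce a label vector to a 1-D int array and validate its range.

    Labels are per-cell integer cluster assignments.  When *k* is given the
    labels must lie in ``{0..k-1}``.
    """
    y = np.asarray(y)
    if y.ndim != 1:
        raise DataValidationError("label vector must be 1-D")
    if y.size and not np.issubdtype(y.dtype, np.integer):
        if not np.allclose(y, np.round(y)):
            raise DataValidationError("labels must be integers")
    y = y.astype(int)
    if n_cells is not None and y.size != n_cells:
        raise DataValidationError(f"{y.size} labels for {n_cells} cells")
    if y.size and y.min() < 0:
        raise DataValidationError("labels must be nonnegative")
    if k is not None and y.size and y.max() >= k:
        raise DataValidationError(f"label {y.max()} out of range for k={k}")
    return y
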