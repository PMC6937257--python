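"""Quality-control filtering, log transformation and gene-space alignment.

The pipeline applied to every dataset (source and target separately,
once, before any clustering method) is:

1. **Cell filter** — drop cells with fewer than ``min_genes`` genes
   detected above ``expression_threshold``.
2. **Gene filter** — drop *ubiquitous* genes (detected above the threshold
   in at least ``prevalence_pct`` % of cells) and *rare* genes (below the
   threshold in at least ``prevalence_pct`` % of cells).
3. **Log transform** — ``log2(x + 1)`` entrywise.

Both detection tests use strict inequalities; the prevalence test
("at least") is non-strict.  Filters are idempotent.  When two datasets
must share a feature space, :func:`intersect_genes` restricts both to the
common genes in a single consistent order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import ExpressionMatrix
from .errors import DataValidationError, EmptyResultError


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cell and gene filters.

    Defaults suit log-scale TPM/CPM data with many zeros; real datasets
    need thresholds chosen from their expression histograms, so override
    them per dataset.

    Attributes
    ----------
    min_genes
        Minimum number of detected genes a cell must have (cell filter).
    expression_threshold
        Detection threshold: a gene counts as detected in a cell when its
        value is strictly greater than this.
    prevalence_pct
        Percentage of cells (0 < p < 100) at which a gene is called
        ubiquitous (detected in >= p% of cells) or rare (below threshold
        in >= p% of cells).
    """

    min_genes: int = 2000
    expression_threshold: float = 0.0
    prevalence_pct: float = 94.0

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise DataValidationError("min_genes must be >= 1")
        if not (0.0 < self.prevalence_pct < 100.0):
            raise DataValidationError("prevalence_pct must be in (0, 100)")


def cell_filter(X: ExpressionMatrix, cfg: FilterConfig) -> ExpressionMatrix:
    """Remove cells with fewer than ``cfg.min_genes`` detected genes.

    A gene is detected in a cell when its value is strictly greater than
    ``cfg.expression_threshold``.  Gene set and cell order are preserved.
    """
    if X.n_cells == 0:
        raise DataValidationError("empty matrix")
    detected = (X.values > cfg.expression_threshold).sum(axis=0)
    keep = detected >= cfg.min_genes
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell")
    return X.subset_cells(np.flatnonzero(keep))


def gene_filter(X: ExpressionMatrix, cfg: FilterConfig) -> ExpressionMatrix:
    """Remove ubiquitous and rare genes.

    Ubiquitous: value strictly above the threshold in at least
    ``prevalence_pct`` % of cells.  Rare: value strictly below the
    threshold in at least ``prevalence_pct`` % of cells.  Gene order is
    preserved.
    """
    if X.n_genes == 0:
        raise DataValidationError("empty matrix")
    n = X.n_cells
    cutoff = cfg.prevalence_pct / 100.0 * n
    above = (X.values > cfg.expression_threshold).sum(axis=1)
    below = (X.values < cfg.expression_threshold).sum(axis=1)
    drop = (above >= cutoff) | (below >= cutoff)
    if drop.all():
        raise EmptyResultError("gene filter removed every gene")
    return X.subset_genes(np.flatnonzero(~drop))


def log_transform(X: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Replace every entry v by ``log_base(v + 1)`` and tag the unit as log.

    Applying the transform to an already log-tagged matrix is an error.
    """
    if X.unit == "log":
        raise DataValidationError("matrix is already log-transformed")
    if base <= 1.0:
        raise DataValidationError("log base must exceed 1")
    values = np.log1p(X.values) / np.log(base)
    return replace(X, values=values, unit="log")


def intersect_genes(
    A: ExpressionMatrix, B: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, identically ordered.

    The output keeps A's gene order on the intersection and reorders B's
    rows to match, so the two matrices can be used together by any method
    that assumes aligned feature spaces.
    """
    common = set(A.gene_ids) & set(B.gene_ids)
    if not common:
        raise EmptyResultError("no genes shared between the two matrices")
    a_index = [i for i, g in enumerate(A.gene_ids) if g in common]
    order = {g: i for i, g in enumerate(B.gene_ids)}
    b_index = [order[A.gene_ids[i]] for i in a_index]
    return A.subset_genes(a_index), B.subset_genes(b_index)


def preprocess(
    X: ExpressionMatrix,
    cfg: FilterConfig | None = None,
    log: bool = True,
    log_base: float = 2.0,
) -> ExpressionMatrix:
    """Run the full pipeline: cell filter, gene filter, log transform.

    ``cfg=None`` skips both filters (appropriate for data with few zeros,
    e.g. simulated counts, where prevalence filters are uninformative).
    """
    if cfg is not None:
        X = cell_filter(X, cfg)
        X = gene_filter(X, cfg)
    if log and X.unit != "log":
        X = log_transform(X, base=log_base)
    return X
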