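"""End-to-end dictionary transfer: mixing, theta selection, clustering.

Workflow (given aligned gene spaces):

1. fit the elastic-net NMF on the source (warm-started from labels when
   available, otherwise labels are first manufactured by NMF clustering);
2. project the target onto the source dictionary and binarize the
   loadings into hard assignments W';
3. for each theta on a grid, build the mixed target
   ``X_new = theta * H W' + (1 - theta) * X_trg``, cluster it, and score
   the predicted labels by kernel target alignment against a data kernel
   (the untouched target by default; optionally the mixed dataset);
4. keep the theta with the best alignment (ties to the smallest theta).

theta = 0 reproduces plain clustering of the untouched target; theta = 1
clusters the pure dictionary reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError, NumericalError
from .kta import alignment
from .nmf import (
    NMFConfig,
    binarize_assignments,
    fit_source_nmf,
    mix_target,
    nmf_cluster_labels,
    transfer_weights,
)
from .sc3 import SC3Config, consensus_cluster

# Pre-specified mixture grid: endpoints are excluded because both are
# degenerate for model selection (theta=0 scores labels on the data they
# were fitted to; theta=1 discards the target entirely, and its k-point
# reconstruction aligns with its own clustering no matter how poorly the
# dictionary fits).  mix_target itself supports the full closed interval.
DEFAULT_THETA_GRID = tuple(np.round(np.linspace(0.1, 0.9, 9), 10))


@dataclass(frozen=True)
class TransferConfig:
    """Settings for the transfer pipeline.

    ``clusterer`` maps a mixed expression matrix to a label vector; when
    None an SC3 consensus clusterer built from ``sc3`` is used.
    ``center_kernels`` switches the alignment score to double-centered
    kernels (mean component removed before comparing), which makes the
    score sensitive to cluster structure rather than overall expression
    magnitude.  ``score_kernel`` selects the data kernel the predicted
    labels are aligned against: the candidate mixed dataset (``mixed``)
    or the untouched target (``target``).  Scoring on the mixed dataset
    is self-fulfilling as theta -> 1 (the mixture degenerates to the
    k-point dictionary reconstruction, whose clustering trivially aligns
    with its own kernel, whether or not the dictionary fits the target);
    scoring on the target keeps the selection honest, so it is the
    default.
    """

    nmf: NMFConfig
    sc3: SC3Config | None = None
    clusterer: Callable[[ExpressionMatrix], np.ndarray] | None = None
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    center_kernels: bool = True
    score_kernel: str = "target"

    def __post_init__(self) -> None:
        grid = tuple(self.theta_grid)
        if not grid:
            raise DataValidationError("theta grid must be non-empty")
        if len(set(grid)) != len(grid):
            raise DataValidationError("theta grid values must be unique")
        if min(grid) < 0 or max(grid) > 1:
            raise DataValidationError("theta grid values must lie in [0, 1]")
        if self.score_kernel not in ("target", "mixed"):
            raise DataValidationError("score_kernel must be 'target' or 'mixed'")
        if self.clusterer is None and self.sc3 is None:
            raise DataValidationError("provide either an SC3Config or a clusterer")

    def make_clusterer(self) -> Callable[[ExpressionMatrix], np.ndarray]:
        if self.clusterer is not None:
            return self.clusterer
        sc3 = self.sc3
        return lambda X: consensus_cluster(X, sc3)


def select_theta(
    X_trg: ExpressionMatrix,
    H_src: np.ndarray,
    W_prime: np.ndarray,
    cfg: TransferConfig,
):
    """Grid-search theta by unsupervised kernel target alignment.

    Returns ``(theta_star, X_new, labels, scores)`` where scores maps
    each successfully clustered theta to its KTA score.  A clusterer
    failure at one grid point is skipped with a warning; if every grid
    point fails a NumericalError is raised.
    """
    clusterer = cfg.make_clusterer()
    scores: dict[float, float] = {}
    best = None  # (score, theta, X_new, labels)
    for theta in sorted(cfg.theta_grid):
        X_new = mix_target(X_trg, H_src, W_prime, theta)
        try:
            labels = validate_labels(clusterer(X_new), n_cells=X_trg.n_cells)
            score_data = X_trg if cfg.score_kernel == "target" else X_new
            score = alignment(score_data, labels, center=cfg.center_kernels)
        except Exception as exc:  # clusterer or scoring failure at this theta
            warnings.warn(f"clustering failed at theta={theta}: {exc}", RuntimeWarning)
            continue
        scores[float(theta)] = score
        if best is None or score > best[0]:
            best = (score, float(theta), X_new, labels)
    if best is None:
        raise NumericalError("clustering failed at every theta grid point")
    _, theta_star, X_new, labels = best
    return theta_star, X_new, labels, scores


def transfer_cluster(
    X_src: ExpressionMatrix,
    y_src,
    X_trg: ExpressionMatrix,
    cfg: TransferConfig,
):
    """Full pipeline; returns ``(labels, theta_star, diagnostics)``.

    Gene spaces must already be intersected and aligned.  When *y_src* is
    None, source labels are first produced by NMF clustering and then
    treated as if they were real labels.
    """
    if X_src.n_genes != X_trg.n_genes:
        raise DataValidationError("source and target gene spaces are not aligned")
    if list(X_src.gene_ids) != list(X_trg.gene_ids):
        raise DataValidationError("source and target gene ids differ or are reordered")

    if y_src is None:
        y_src = nmf_cluster_labels(X_src, cfg.nmf)
    y_src = validate_labels(y_src, n_cells=X_src.n_cells, k=cfg.nmf.k)

    pair = fit_source_nmf(X_src, y=y_src, cfg=cfg.nmf)
    W_trg = transfer_weights(X_trg, pair.H)
    W_prime = binarize_assignments(W_trg)
    theta_star, X_new, labels, scores = select_theta(X_trg, pair.H, W_prime, cfg)
    diagnostics = {
        "factorization": pair,
        "W_trg": W_trg,
        "W_prime": W_prime,
        "kta_scores": scores,
        "X_new": X_new,
        "y_src": y_src,
    }
    return labels, theta_star, diagnostics
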