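"""SC3-style consensus clustering.

The clusterer follows the single-cell consensus clustering recipe:

1. pairwise cell-cell distance matrices (Euclidean, 1 - Pearson,
   1 - Spearman);
2. spectral transformations of each distance matrix (PCA scores, or
   eigenvectors of the normalized graph Laplacian of the similarity
   ``exp(-D / max(D))``), truncated at several dimensionalities ``d``;
3. k-means on every (metric, transform, d) embedding;
4. the binary co-clustering matrices are averaged into a consensus
   matrix, which is hierarchically clustered (complete linkage on
   1 - consensus) and cut at k.

By SC3 convention the ``d`` grid spans 4-7 % of the number of cells; the
default here takes up to four evenly spaced values from that range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import pairwise_distances
from sklearn.utils.extmath import randomized_svd

from .data import ExpressionMatrix
from .errors import DataValidationError, NumericalError

METRICS = ("euclidean", "pearson", "spearman")
TRANSFORMS = ("pca", "laplacian")


@dataclass(frozen=True)
class SC3Config:
    """Configuration of the consensus clusterer."""

    k: int
    metrics: tuple[str, ...] = METRICS
    transforms: tuple[str, ...] = TRANSFORMS
    d_range: tuple[int, ...] | None = None  # None -> mid 4-7 % of n
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DataValidationError("k must be positive")
        if not self.metrics or any(m not in METRICS for m in self.metrics):
            raise DataValidationError(f"metrics must be a non-empty subset of {METRICS}")
        if not self.transforms or any(t not in TRANSFORMS for t in self.transforms):
            raise DataValidationError(f"transforms must be a non-empty subset of {TRANSFORMS}")
        if self.d_range is not None and (not self.d_range or min(self.d_range) < 1):
            raise DataValidationError("d_range must contain positive integers")
        if self.kmeans_restarts < 1:
            raise DataValidationError("kmeans_restarts must be positive")


def default_d_range(n_cells: int, max_values: int = 1) -> tuple[int, ...]:
    """Embedding sizes spanning 4-7 % of n (clipped to [2, n-1]).

    By default a single mid-range value (~5.5 % of n) is used, keeping the
    consensus ensemble at one k-means run per metric/transform pair; raise
    ``max_values`` for a denser (more stable, slower) ensemble.
    """
    lo = max(2, int(np.floor(0.04 * n_cells)))
    hi = max(lo, int(np.ceil(0.07 * n_cells)))
    hi = min(hi, n_cells - 1)
    lo = min(lo, hi)
    return tuple(np.unique(np.linspace(lo, hi, max_values).round().astype(int)))


def distance_matrices(X, metrics=METRICS) -> list[np.ndarray]:
    """Cell-cell distance matrices; correlation distances are 1 - r.

    A constant cell vector has undefined correlation; its correlation is
    treated as 0 (distance 1), except on the diagonal which stays 0.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if V.shape[1] < 2:
        raise DataValidationError("need at least two cells")
    out = []
    for metric in metrics:
        if metric == "euclidean":
            D = pairwise_distances(V.T.astype(np.float32), metric="euclidean")
        elif metric in ("pearson", "spearman"):
            M = V if metric == "pearson" else scipy.stats.rankdata(V, axis=0)
            D = 1.0 - _column_correlation(M)
            np.fill_diagonal(D, 0.0)
        else:
            raise DataValidationError(f"unknown metric {metric!r}")
        D = D.astype(float)
        out.append((D + D.T) / 2.0)
    return out


def _column_correlation(M: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns (float32 BLAS path)."""
    C = M.astype(np.float32)
    C = C - C.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.sum(C * C, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (C.T @ C) / np.outer(norms, norms)
    return np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)


def transform_distance(D: np.ndarray, transform: str, d: int) -> np.ndarray:
    """Embed a distance matrix into d dimensions (see module docstring)."""
    return _transform_full(D, transform, d)[:, :d]


def _transform_full(D: np.ndarray, transform: str, d_max: int) -> np.ndarray:
    """Compute the first d_max embedding dimensions (callers slice)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if d_max >= n:
        raise DataValidationError("embedding dimension must be below the cell count")
    try:
        if transform == "pca":
            # PCA scores of the distance matrix, rows as observations
            C = D - D.mean(axis=0, keepdims=True)
            if d_max < n // 2 and n > 200:
                U, s, _ = randomized_svd(C, n_components=d_max, random_state=0)
                return U * s
            _, s, Vt = scipy.linalg.svd(C, full_matrices=False)
            return C @ Vt[:d_max].T
        if transform == "laplacian":
            scale = D.max()
            A = np.exp(-D / scale) if scale > 0 else np.ones_like(D)
            deg = A.sum(axis=1)
            inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, np.finfo(float).tiny))
            L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
            _, vecs = scipy.linalg.eigh(
                L.astype(np.float32), subset_by_index=[0, d_max - 1]
            )
            return vecs.astype(float)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            f"degenerate eigenproblem in {transform} transform "
            f"(n={n}, condition-related failure): {exc}"
        ) from exc
    raise DataValidationError(f"unknown transform {transform!r}")


def consensus_cluster(
    X, cfg: SC3Config, return_consensus: bool = False
):
    """Run the full consensus pipeline on a genes x cells matrix.

    Returns the 0-based label vector, and optionally the n x n consensus
    matrix (symmetric, unit diagonal, entries in [0, 1]).
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n = V.shape[1]
    if cfg.k > n:
        raise DataValidationError(f"k={cfg.k} exceeds the number of cells {n}")
    d_range = cfg.d_range or default_d_range(n)
    if max(d_range) >= n:
        raise DataValidationError("max(d_range) must be below the cell count")

    consensus = np.zeros((n, n))
    n_runs = 0
    run_seed = np.random.SeedSequence(cfg.seed)
    Ds = distance_matrices(V, cfg.metrics)
    for D in Ds:
        for transform in cfg.transforms:
            emb_full = _transform_full(D, transform, max(d_range))
            for d in d_range:
                seed = int(run_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
                km = KMeans(
                    n_clusters=cfg.k,
                    n_init=cfg.kmeans_restarts,
                    random_state=seed,
                )
                with warnings.catch_warnings():
                    # duplicate embedded points (e.g. identical cells) can
                    # yield fewer than k distinct centroids; that is fine
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    labels = km.fit_predict(emb_full[:, :d])
                consensus += (labels[:, None] == labels[None, :])
                n_runs += 1
    consensus /= n_runs

    condensed = squareform(1.0 - consensus, checks=False)
    Z = linkage(condensed, method="complete")
    # cut to exactly k groups (fcluster's maxclust criterion can collapse
    # to fewer clusters when merge heights tie)
    labels = cut_tree(Z, n_clusters=min(cfg.k, n)).ravel()
    if return_consensus:
        return labels, consensus
    return labels
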