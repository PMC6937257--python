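"""Elastic-net regularized NMF and the dictionary-transfer primitives.

The source expression matrix ``X_src`` (genes x cells, nonnegative, after
log transform) is factorized as ``X_src ~ H W`` with a genes x k
dictionary ``H`` and a k x cells loading matrix ``W``, minimizing

    1/2 ||X - HW||_F^2
      + alpha * lam * (||vec(H)||_1 + ||vec(W)||_1)
      + alpha/2 * (1 - lam) * (||H||_F^2 + ||W||_F^2)

subject to H, W >= 0.  The solver is HALS-style block coordinate descent:
each column of H (row of W) has a closed-form nonnegative minimizer, so
the objective is non-increasing at every update.

When source labels are available, W is initialized with their one-hot
encoding so the dictionary columns start aligned to known cell types.
The dictionary is cell-count independent and is transferred to a target
dataset by a nonnegative least-squares solve for the target loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of the factorization.

    k is the number of dictionary atoms (clusters); alpha scales the
    elastic-net penalty and lam in [0, 1] mixes L1 (lam=1) against L2
    (lam=0).
    """

    k: int
    alpha: float = 1.0
    lam: float = 0.5
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DataValidationError("k must be a positive integer")
        if self.alpha < 0:
            raise DataValidationError("alpha must be nonnegative")
        if not 0.0 <= self.lam <= 1.0:
            raise DataValidationError("lam must lie in [0, 1]")
        if self.max_iter < 1 or self.tol <= 0:
            raise DataValidationError("max_iter must be >= 1 and tol > 0")


@dataclass
class FactorPair:
    """A fitted factorization: dictionary H (genes x k), loadings W (k x cells)."""

    H: np.ndarray
    W: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _as_values(X) -> np.ndarray:
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if (V < 0).any():
        raise DataValidationError("NMF requires nonnegative input")
    return V


def nmf_objective(X, H: np.ndarray, W: np.ndarray, alpha: float, lam: float) -> float:
    """Evaluate the elastic-net NMF objective at (H, W)."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    resid = V - H @ W
    return float(
        0.5 * np.sum(resid * resid)
        + alpha * lam * (np.abs(H).sum() + np.abs(W).sum())
        + 0.5 * alpha * (1.0 - lam) * (np.sum(H * H) + np.sum(W * W))
    )


def one_hot_init(y, k: int) -> np.ndarray:
    """One-hot encode labels into a k x n assignment matrix.

    Entry (j, i) is 1 iff cell i carries label j; every column sums to 1.
    """
    y = validate_labels(y, k=k)
    W = np.zeros((k, y.size))
    W[y, np.arange(y.size)] = 1.0
    return W


def _hals_H(V, H, W, XWt, WWt, l1, l2) -> None:
    for j in range(H.shape[1]):
        denom = WWt[j, j] + l2
        if denom <= 0:
            H[:, j] = 0.0
            continue
        numer = XWt[:, j] - H @ WWt[:, j] + H[:, j] * WWt[j, j] - l1
        H[:, j] = np.maximum(numer / denom, 0.0)


def _hals_W(V, H, W, HtX, HtH, l1, l2) -> None:
    for j in range(W.shape[0]):
        denom = HtH[j, j] + l2
        if denom <= 0:
            W[j, :] = 0.0
            continue
        numer = HtX[j, :] - HtH[j, :] @ W + HtH[j, j] * W[j, :] - l1
        W[j, :] = np.maximum(numer / denom, 0.0)


def fit_source_nmf(X, y=None, cfg: NMFConfig | None = None) -> FactorPair:
    """Fit the elastic-net NMF, optionally warm-started from labels.

    Parameters
    ----------
    X
        Nonnegative genes x cells matrix (ExpressionMatrix or array).
    y
        Optional integer cluster labels in {0..k-1}; when given, W starts
        from their one-hot encoding, anchoring dictionary columns to the
        labeled cell types.  When absent, both factors start from a
        seeded uniform random draw.
    """
    if cfg is None:
        raise DataValidationError("an NMFConfig is required")
    V = _as_values(X)
    g, n = V.shape
    k = cfg.k
    l1 = cfg.alpha * cfg.lam
    l2 = cfg.alpha * (1.0 - cfg.lam)

    if y is not None:
        W = one_hot_init(validate_labels(y, n_cells=n, k=k), k)
        H = np.zeros((g, k))
    else:
        rng = np.random.default_rng(cfg.seed)
        scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
        H = scale * rng.random((g, k))
        W = scale * rng.random((k, n))

    trace: list[float] = []
    prev = np.inf
    converged = False
    it = 0
    xnorm2 = float(np.sum(V * V))
    for it in range(1, cfg.max_iter + 1):
        WWt = W @ W.T
        XWt = V @ W.T
        _hals_H(V, H, W, XWt, WWt, l1, l2)
        HtH = H.T @ H
        HtX = H.T @ V
        _hals_W(V, H, W, HtX, HtH, l1, l2)
        # Frobenius term via the Gram identity (avoids forming the residual):
        # ||X-HW||^2 = ||X||^2 - 2<W,H'X> + <H'H, WW'>
        fro2 = xnorm2 - 2.0 * float(np.sum(W * HtX)) + float(np.sum(W * (HtH @ W)))
        obj = (
            0.5 * max(fro2, 0.0)
            + l1 * (np.abs(H).sum() + np.abs(W).sum())
            + 0.5 * l2 * (np.sum(H * H) + np.sum(W * W))
        )
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= cfg.tol * max(abs(prev), 1e-12):
            converged = True
            break
        prev = obj
    if not converged:
        warnings.warn(
            f"NMF did not converge in {cfg.max_iter} iterations "
            f"(final objective {trace[-1]:.6g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return FactorPair(H=H, W=W, objective_trace=trace, converged=converged, n_iter=it)


def nmf_cluster_labels(X, cfg: NMFConfig) -> np.ndarray:
    """Cluster cells by NMF: label of cell i is the argmax row of W[:, i].

    Used to manufacture source labels when none are provided; ties break
    to the lowest row index.
    """
    pair = fit_source_nmf(X, y=None, cfg=cfg)
    return np.argmax(pair.W, axis=0)


def transfer_weights(
    X_trg,
    H_src: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> np.ndarray:
    """Project a target dataset onto a fixed source dictionary.

    Solves ``min_W 1/2 ||X_trg - H_src W||_F^2`` subject to W >= 0 by
    block coordinate descent over the rows of W (each row has a
    closed-form nonnegative update, so the loss is monotone).
    """
    V = _as_values(X_trg)
    H = np.asarray(H_src, dtype=float)
    if V.shape[0] != H.shape[0]:
        raise DataValidationError(
            f"gene dimension mismatch: target has {V.shape[0]} genes, dictionary {H.shape[0]}"
        )
    k = H.shape[1]
    W = np.zeros((k, V.shape[1]))
    HtH = H.T @ H
    HtX = H.T @ V
    prev = np.inf
    for _ in range(max_iter):
        _hals_W(V, H, W, HtX, HtH, 0.0, 0.0)
        obj = 0.5 * np.sum(W * (HtH @ W)) - np.sum(W * HtX)
        if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1e-12):
            break
        prev = obj
    return W


def binarize_assignments(W: np.ndarray) -> np.ndarray:
    """Reduce loadings to hard assignments: 1 at each column-wise maximum.

    Exactly one 1 per column; ties resolve to the lowest row index.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] < 1:
        raise DataValidationError("W must be a 2-D matrix with at least one row")
    out = np.zeros_like(W)
    out[np.argmax(W, axis=0), np.arange(W.shape[1])] = 1.0
    return out


def mix_target(X_trg, H_src: np.ndarray, W_prime: np.ndarray, theta: float):
    """Convex combination of the dictionary reconstruction and the target.

    ``X_new = theta * H_src @ W_prime + (1 - theta) * X_trg``.  theta=0
    returns the target unchanged; theta=1 returns the pure reconstruction.
    """
    if not 0.0 <= theta <= 1.0:
        raise DataValidationError("theta must lie in [0, 1]")
    V = X_trg.values if isinstance(X_trg, ExpressionMatrix) else np.asarray(X_trg, dtype=float)
    mixed = theta * (H_src @ W_prime) + (1.0 - theta) * V
    if isinstance(X_trg, ExpressionMatrix):
        return ExpressionMatrix(
            values=mixed,
            gene_ids=X_trg.gene_ids.copy(),
            cell_ids=X_trg.cell_ids.copy(),
            unit=X_trg.unit,
        )
    return mixed
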