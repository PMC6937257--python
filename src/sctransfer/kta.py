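"""Kernel target alignment (KTA) utilities.

KTA measures the similarity of two kernel matrices as their normalized
Frobenius inner product and serves here as an *unsupervised* proxy for
clustering quality: the linear kernel of a (mixed) expression matrix over
cells is aligned against the label kernel of the predicted clustering.
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionMatrix
from .errors import DataValidationError
from .nmf import one_hot_init


def linear_kernel(X) -> np.ndarray:
    """Uncentered linear kernel over cells: ``K = X^T X`` (n x n)."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    return V.T @ V


def label_kernel(y, k: int | None = None) -> np.ndarray:
    """Linear kernel of one-hot labels: 1 where two cells share a label."""
    y = np.asarray(y, dtype=int)
    if k is None:
        k = int(y.max()) + 1 if y.size else 1
    L = one_hot_init(y, k)
    return L.T @ L


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a kernel matrix (feature-space mean removal)."""
    K = np.asarray(K, dtype=float)
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def kta_score(K1: np.ndarray, K2: np.ndarray) -> float:
    """Normalized Frobenius alignment ``<K1,K2> / (||K1|| ||K2||)``.

    Lies in [0, 1] for PSD inputs, with 1 iff the kernels are
    proportional.  Raises on a zero-norm kernel.
    """
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    if K1.shape != K2.shape or K1.ndim != 2 or K1.shape[0] != K1.shape[1]:
        raise DataValidationError("kernels must be square matrices of equal shape")
    n1 = np.linalg.norm(K1)
    n2 = np.linalg.norm(K2)
    if n1 == 0 or n2 == 0:
        raise DataValidationError("zero-norm kernel")
    return float(np.sum(K1 * K2) / (n1 * n2))


def alignment(X, y, k: int | None = None, center: bool = False) -> float:
    """KTA between an expression matrix's cell kernel and a labeling.

    A degenerate single-cluster labeling has a zero centered label kernel
    and carries no alignment information; it scores 0.
    """
    K1 = linear_kernel(X)
    K2 = label_kernel(y, k)
    if center:
        K1 = center_kernel(K1)
        K2 = center_kernel(K2)
        if np.linalg.norm(K2) == 0 or np.linalg.norm(K1) == 0:
            return 0.0
    return kta_score(K1, K2)
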