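"""Model/Results interface for the transfer clustering method.

:class:`TransferClusterModel` is constructed from a target and a source
expression matrix (plus optional source labels); :meth:`~TransferClusterModel.fit`
runs the dictionary transfer and returns a :class:`TransferClusterResults`
carrying the predicted target labels, the selected mixture parameter, the
KTA score profile and the fitted factorization, with ``summary()`` and
plotting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError
from .nmf import NMFConfig
from .sc3 import SC3Config
from .transfer import DEFAULT_THETA_GRID, TransferConfig, transfer_cluster


class TransferClusterModel:
    """Transfer-learning clustering of a target dataset.

    Parameters
    ----------
    target
        Unlabeled genes x cells target matrix (log scale recommended).
    source
        Labeled reference matrix over the same gene space (same ids, same
        order; use :func:`sctransfer.preprocess.intersect_genes` first).
    source_labels
        Integer cluster labels for the source cells; when omitted they
        are generated by NMF clustering of the source.
    n_clusters
        Number of clusters for the target; defaults to the dictionary
        size (the number of distinct source labels).
    dictionary_size
        Number of NMF dictionary atoms; defaults to the number of
        distinct source labels (required when labels are omitted).
    theta_grid
        Candidate mixture parameters in [0, 1].
    alpha, lam
        Elastic-net penalty multiplier and L1/L2 mixing for the NMF.
    center_kernels
        Use double-centered kernels in the theta-selection score.
    seed
        Seed for all stochastic stages (NMF random init, k-means).
    """

    def __init__(
        self,
        target: ExpressionMatrix,
        source: ExpressionMatrix,
        source_labels=None,
        *,
        n_clusters: int | None = None,
        dictionary_size: int | None = None,
        theta_grid=DEFAULT_THETA_GRID,
        alpha: float = 1.0,
        lam: float = 0.5,
        nmf_max_iter: int = 500,
        nmf_tol: float = 1e-5,
        sc3_config: SC3Config | None = None,
        center_kernels: bool = True,
        seed: int = 0,
    ) -> None:
        if list(target.gene_ids) != list(source.gene_ids):
            raise DataValidationError(
                "target and source must share an identically ordered gene space"
            )
        self.target = target
        self.source = source
        if source_labels is not None:
            source_labels = validate_labels(source_labels, n_cells=source.n_cells)
            labels_0based = np.unique(source_labels, return_inverse=True)[1]
            k_dict = dictionary_size or int(labels_0based.max()) + 1
            self.source_labels = labels_0based
        else:
            if dictionary_size is None:
                raise DataValidationError(
                    "dictionary_size is required when source labels are absent"
                )
            k_dict = dictionary_size
            self.source_labels = None
        self.k_dictionary = k_dict
        self.n_clusters = n_clusters or k_dict
        nmf = NMFConfig(
            k=k_dict, alpha=alpha, lam=lam, max_iter=nmf_max_iter, tol=nmf_tol, seed=seed
        )
        sc3 = sc3_config or SC3Config(k=self.n_clusters, seed=seed)
        if sc3.k != self.n_clusters:
            raise DataValidationError("sc3_config.k must equal n_clusters")
        self.config = TransferConfig(
            nmf=nmf, sc3=sc3, theta_grid=tuple(theta_grid), center_kernels=center_kernels
        )
        self.seed = seed

    @classmethod
    def from_dataframes(
        cls, target: pd.DataFrame, source: pd.DataFrame, source_labels=None, **kwargs
    ) -> "TransferClusterModel":
        """Build from genes x cells DataFrames (index gene ids, columns cells)."""
        return cls(
            ExpressionMatrix.from_dataframe(target, unit="log"),
            ExpressionMatrix.from_dataframe(source, unit="log"),
            source_labels,
            **kwargs,
        )

    def fit(self) -> "TransferClusterResults":
        """Run the transfer pipeline and return the results object."""
        labels, theta, diagnostics = transfer_cluster(
            self.source, self.source_labels, self.target, self.config
        )
        return TransferClusterResults(self, labels, theta, diagnostics)


class TransferClusterResults:
    """Fitted results: target labels, selected theta, diagnostics."""

    def __init__(self, model: TransferClusterModel, labels, theta, diagnostics) -> None:
        self.model = model
        self.labels_ = np.asarray(labels, dtype=int)
        self.theta_ = float(theta)
        self.kta_scores_ = dict(diagnostics["kta_scores"])
        self.dictionary_ = diagnostics["factorization"].H
        self.source_loadings_ = diagnostics["factorization"].W
        self.target_loadings_ = diagnostics["W_trg"]
        self.assignments_ = diagnostics["W_prime"]
        self.mixed_target_ = diagnostics["X_new"]
        self.source_labels_used_ = diagnostics["y_src"]
        self.objective_trace_ = diagnostics["factorization"].objective_trace
        self.nmf_converged_ = diagnostics["factorization"].converged

    # -- tabular views --------------------------------------------------
    def score_table(self) -> pd.DataFrame:
        """KTA score per candidate theta, flagging the selected value."""
        thetas = sorted(self.kta_scores_)
        return pd.DataFrame(
            {
                "theta": thetas,
                "kta": [self.kta_scores_[t] for t in thetas],
                "selected": [t == self.theta_ for t in thetas],
            }
        )

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels_).value_counts().sort_index()

    def predicted_labels(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.model.target.cell_ids, name="cluster")

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        lines = [
            "Transfer clustering results",
            "===========================",
            f"genes (aligned):        {m.target.n_genes}",
            f"source cells:           {m.source.n_cells}",
            f"target cells:           {m.target.n_cells}",
            f"dictionary atoms (k):   {m.k_dictionary}",
            f"target clusters:        {m.n_clusters}",
            f"elastic net alpha/lam:  {m.config.nmf.alpha:g} / {m.config.nmf.lam:g}",
            f"NMF iterations:         {len(self.objective_trace_)}"
            + ("" if self.nmf_converged_ else " (not converged)"),
            f"selected theta:         {self.theta_:g}",
            "",
            "theta   KTA score",
        ]
        for t in sorted(self.kta_scores_):
            marker = "  <- selected" if t == self.theta_ else ""
            lines.append(f"{t:5.2f}   {self.kta_scores_[t]:.6f}{marker}")
        sizes = " ".join(f"{c}:{n}" for c, n in self.cluster_sizes().items())
        lines += ["", f"target cluster sizes:   {sizes}"]
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_kta(self, ax=None):
        """KTA score as a function of theta, selected value marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.score_table()
        ax.plot(tab["theta"], tab["kta"], marker="o")
        ax.axvline(self.theta_, linestyle="--", color="grey")
        ax.set_xlabel(r"mixture parameter $\theta$")
        ax.set_ylabel("kernel target alignment")
        return ax
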