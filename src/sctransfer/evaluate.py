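"""Baselines, ARI scoring, the repetition harness, and robustness counting.

Three methods are compared throughout:

``TargetCluster``
    SC3 consensus clustering of the target dataset alone.
``ConcatenateCluster``
    SC3 on the column-concatenation of source and target; scores use the
    target cells only.
``TransferCluster``
    The dictionary-transfer method with automatic theta selection.

Agreement with ground truth is measured by the adjusted Rand index,
always on the target cells.  The simulation study repeats
generate -> split -> downsample -> cluster -> score and aggregates mean
ARIs with normal-approximation 95 % confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError
from .nmf import NMFConfig, binarize_assignments, fit_source_nmf, transfer_weights
from .preprocess import log_transform
from .sc3 import SC3Config, consensus_cluster
from .simulate import (
    OVERLAP_MODES,
    SimConfig,
    downsample,
    generate_dataset,
    split_source_target,
)
from .transfer import TransferConfig, select_theta

logger = logging.getLogger(__name__)

METHODS = ("TargetCluster", "ConcatenateCluster", "TransferCluster")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement of two partitions, in [-1, 1]."""
    a = validate_labels(np.asarray(a))
    b = validate_labels(np.asarray(b))
    if a.size != b.size:
        raise DataValidationError("label vectors differ in length")
    if a.size < 2:
        raise DataValidationError("need at least two cells")
    return float(adjusted_rand_score(a, b))


def target_cluster(X_trg: ExpressionMatrix, cfg: SC3Config) -> np.ndarray:
    """Baseline: consensus-cluster the target dataset alone."""
    return consensus_cluster(X_trg, cfg)


def concatenate_cluster(
    X_src: ExpressionMatrix, X_trg: ExpressionMatrix, cfg: SC3Config
) -> np.ndarray:
    """Baseline: cluster source+target jointly, return target labels only."""
    if X_src.n_cells == 0:
        return consensus_cluster(X_trg, cfg)
    if X_src.n_genes != X_trg.n_genes or list(X_src.gene_ids) != list(X_trg.gene_ids):
        raise DataValidationError("source and target gene spaces are not aligned")
    values = np.hstack([X_src.values, X_trg.values])
    labels = consensus_cluster(values, cfg)
    return labels[X_src.n_cells :]


# ---------------------------------------------------------------------------
# repetition harness


@dataclass
class ExperimentResult:
    """Long-format per-repetition results plus aggregation helpers."""

    results: pd.DataFrame  # columns: repetition, mode, n_trg, method, ari, theta
    n_failures: int = 0

    def aggregate(self, confidence: float = 0.95) -> pd.DataFrame:
        """Mean ARI and CI half-width per (mode, n_trg, method).

        The CI is a normal approximation over repetitions; it is NaN when
        fewer than two repetitions are available.
        """
        z = stats.norm.ppf(0.5 + confidence / 2.0)

        def _agg(g: pd.Series) -> pd.Series:
            n = g.count()
            half = z * g.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan
            return pd.Series({"mean_ari": g.mean(), "ci_halfwidth": half, "n_reps": n})

        out = (
            self.results.groupby(["mode", "n_trg", "method"])["ari"]
            .apply(_agg)
            .unstack()
            .reset_index()
        )
        out["n_reps"] = out["n_reps"].astype(int)
        return out


def run_simulation_study(
    sim: SimConfig,
    modes=("complete",),
    target_sizes=(100, 400),
    n_reps: int = 10,
    seed: int = 0,
    methods=METHODS,
    theta_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    alpha: float = 1.0,
    lam: float = 0.5,
    nmf_max_iter: int = 300,
    nmf_tol: float = 1e-4,
    kmeans_restarts: int = 1,
    center_kernels: bool = True,
) -> ExperimentResult:
    """Repeatedly simulate, split, downsample and score all methods.

    Per repetition a fresh dataset is generated and split under each
    overlap mode (top-node assignment re-randomized each time); each
    requested target size is drawn by uniform downsampling.  Simulated
    data is log-transformed only (counts have almost no zeros, so
    prevalence filters would be uninformative).  The clusterer k is set
    to the number of distinct ground-truth clusters present in each
    dataset; the dictionary size follows the source labels.

    Individual failures are logged and excluded (count in the result).
    """
    if n_reps < 1:
        raise DataValidationError("n_reps must be >= 1")
    for mode in modes:
        if mode not in OVERLAP_MODES:
            raise DataValidationError(f"unknown overlap mode {mode!r}")
    root = np.random.SeedSequence(seed)
    rows = []
    n_failures = 0
    for rep in range(n_reps):
        rep_ss = root.spawn(1)[0]
        data = generate_dataset(sim, rep_ss.spawn(1)[0])
        for mode in modes:
            try:
                src, trg_full = split_source_target(
                    data, mode, sim.n_src, max(target_sizes), rep_ss.spawn(1)[0],
                    strict=False,
                )
            except DataValidationError as exc:
                logger.warning("rep %d mode %s split failed: %s", rep, mode, exc)
                n_failures += len(target_sizes) * len(methods)
                continue
            X_src = log_transform(src.X)
            y_src = np.unique(src.y, return_inverse=True)[1]
            k_src = int(y_src.max()) + 1
            source_factors = None
            if "TransferCluster" in methods:
                # label-warm-started fit is deterministic; share across sizes
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    source_factors = fit_source_nmf(
                        X_src,
                        y=y_src,
                        cfg=NMFConfig(
                            k=k_src, alpha=alpha, lam=lam,
                            max_iter=nmf_max_iter, tol=nmf_tol,
                        ),
                    )
            for n_trg in target_sizes:
                trg = downsample(trg_full, min(n_trg, trg_full.n_cells), rep_ss.spawn(1)[0])
                X_trg = log_transform(trg.X)
                k_trg = len(np.unique(trg.y))
                k_all = len(np.unique(np.concatenate([src.y, trg.y])))
                method_seed = int(rep_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                for method in methods:
                    theta = np.nan
                    try:
                        if method == "TargetCluster":
                            labels = target_cluster(
                                X_trg,
                                SC3Config(
                                    k=k_trg, kmeans_restarts=kmeans_restarts, seed=method_seed
                                ),
                            )
                        elif method == "ConcatenateCluster":
                            labels = concatenate_cluster(
                                X_src,
                                X_trg,
                                SC3Config(
                                    k=k_all, kmeans_restarts=kmeans_restarts, seed=method_seed
                                ),
                            )
                        elif method == "TransferCluster":
                            cfg = TransferConfig(
                                nmf=NMFConfig(k=k_src, alpha=alpha, lam=lam, seed=method_seed),
                                sc3=SC3Config(
                                    k=k_trg, kmeans_restarts=kmeans_restarts, seed=method_seed
                                ),
                                theta_grid=tuple(theta_grid),
                                center_kernels=center_kernels,
                            )
                            W_trg = transfer_weights(X_trg, source_factors.H)
                            W_prime = binarize_assignments(W_trg)
                            theta, _, labels, _ = select_theta(
                                X_trg, source_factors.H, W_prime, cfg
                            )
                        else:
                            raise DataValidationError(f"unknown method {method!r}")
                        ari = adjusted_rand_index(trg.y, labels)
                    except Exception as exc:
                        logger.warning(
                            "rep %d mode %s n=%d %s failed: %s", rep, mode, n_trg, method, exc
                        )
                        n_failures += 1
                        continue
                    rows.append(
                        {
                            "repetition": rep,
                            "mode": mode,
                            "n_trg": n_trg,
                            "method": method,
                            "ari": ari,
                            "theta": theta,
                        }
                    )
    return ExperimentResult(results=pd.DataFrame(rows), n_failures=n_failures)


# ---------------------------------------------------------------------------
# robustness counting


@dataclass(frozen=True)
class SeparationCriterion:
    """A predicate on a predicted labeling: reference groups separate.

    The criterion succeeds when the majority predicted cluster of every
    reference group is distinct from that of every other group (the
    groups are "successfully identified" as different populations).
    """

    name: str
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise DataValidationError("need at least two reference groups")
        seen: set[int] = set()
        for grp in self.groups:
            if not grp:
                raise DataValidationError("reference groups must be non-empty")
            if seen & set(grp):
                raise DataValidationError("reference groups must be disjoint")
            seen |= set(grp)

    @classmethod
    def from_cell_ids(cls, name: str, cell_ids, *groups) -> "SeparationCriterion":
        """Build from cell identifier lists instead of integer positions."""
        index = {str(c): i for i, c in enumerate(cell_ids)}
        return cls(name, tuple(tuple(index[str(c)] for c in grp) for grp in groups))

    def satisfied(self, labels) -> bool:
        labels = np.asarray(labels)
        majorities = []
        for grp in self.groups:
            vals, counts = np.unique(labels[list(grp)], return_counts=True)
            majorities.append(vals[np.argmax(counts)])
        return len(set(majorities)) == len(majorities)


def robustness_count(
    method,
    criteria,
    n_reps: int,
    seed: int = 0,
) -> dict[str, int]:
    """Count criterion successes across repeated (reseeded) runs.

    *method* is a callable ``method(seed) -> labels`` wrapping whichever
    clustering pipeline is under study; each repetition uses a fresh
    seed.  A failed repetition counts as non-success for every criterion.
    """
    if n_reps < 1:
        raise DataValidationError("n_reps must be >= 1")
    counts = {c.name: 0 for c in criteria}
    root = np.random.SeedSequence(seed)
    for _ in range(n_reps):
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            labels = method(rep_seed)
        except Exception as exc:
            warnings.warn(f"repetition failed: {exc}", RuntimeWarning)
            continue
        for c in criteria:
            if c.satisfied(labels):
                counts[c.name] += 1
    return counts
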