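"""Hierarchical negative-binomial simulator for single-cell count data.

The generator emulates a tissue with eight cell populations (leaf
clusters 1-8) arranged under five top-level populations (V-Z):

.. code-block:: text

    V    W    X      Y         Z
    |    |    |     / \\      / \\
    1    2    3    4   5     6   *
                                / \\
                               7   8

Every gene starts from a shared background mean drawn from a Gamma
distribution; each cluster in the hierarchy differentially expresses a
random 10-40 % subset of genes with log2 fold changes of magnitude
~ Normal(1, 0.5) and random sign, recursively using the parent cluster's
profile as the new background.  Counts are sampled per cell from a
negative binomial around the (noisy) cell expression profile.

Datasets are split into a labeled source and an unlabeled target under
three overlap regimes (``complete``, ``incomplete``, ``none``) describing
how many top-level populations the two datasets share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ExpressionMatrix, validate_labels
from .errors import DataValidationError

# Nested topology of the simulated hierarchy: a bare integer is a leaf that
# coincides with its top-level cluster; a list is an internal node whose
# children inherit its perturbed profile as background.
TREE_SPEC: tuple = (1, 2, 3, (4, 5), (6, (7, 8)))
TOP_NODE_NAMES: tuple[str, ...] = ("V", "W", "X", "Y", "Z")


def _collect_leaves(node) -> list[int]:
    if isinstance(node, int):
        return [node]
    out: list[int] = []
    for child in node:
        out.extend(_collect_leaves(child))
    return out


@dataclass(frozen=True)
class ClusterTree:
    """The fixed simulation hierarchy: 5 top-level nodes over 8 leaves."""

    spec: tuple = TREE_SPEC
    top_names: tuple[str, ...] = TOP_NODE_NAMES

    @property
    def leaves(self) -> list[int]:
        return _collect_leaves(self.spec)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def top_node_of(self) -> dict[int, str]:
        """Map each leaf cluster id to its top-level node name."""
        return {
            leaf: name
            for name, sub in zip(self.top_names, self.spec)
            for leaf in _collect_leaves(sub)
        }

    def validate(self) -> None:
        if len(self.spec) != len(self.top_names):
            raise DataValidationError("one name per top-level node required")
        leaves = self.leaves
        if sorted(leaves) != list(range(1, len(leaves) + 1)):
            raise DataValidationError("leaves must be 1..n with no repeats")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Defaults reproduce the reference study conditions: 10 000 genes and
    1800 cells per dataset, 1000 source cells, target downsampling grid
    10-800, Dirichlet(10) cluster sizes, Gamma(shape 2, rate 0.1)
    background means, 10-40 % differentially expressed genes per cluster
    with |log2 FC| ~ Normal(1, 0.5), and 10 % multiplicative cell noise.

    ``nb_dispersion`` is the quadratic overdispersion coefficient of the
    counts (variance = mu + nb_dispersion * mu^2).  The conventional
    "dispersion" of R's rnbinom is the gamma-mixing shape (``size``);
    a size of 0.1 corresponds to ``nb_dispersion = 1 / 0.1 = 10``, the
    default here.  This yields ~60 % zero counts, the sparsity regime of
    real droplet scRNA-seq data; ``nb_dispersion = 0`` gives Poisson
    counts.  ``lfc_up_probability`` sets the chance that a
    differentially expressed gene is up- rather than down-regulated; its
    default calibrates the median library size to the reference value of
    ~215 500 reads per cell.
    """

    n_genes: int = 10_000
    n_cells: int = 1_800
    n_src: int = 1_000
    target_sizes: tuple[int, ...] = (10, 50, 100, 200, 400, 600, 800)
    dirichlet_concentration: float = 10.0
    gamma_shape: float = 2.0
    gamma_rate: float = 0.1
    de_fraction_range: tuple[float, float] = (0.10, 0.40)
    lfc_mean: float = 1.0
    lfc_sd: float = 0.5
    lfc_up_probability: float = 0.39
    nb_dispersion: float = 10.0
    cell_noise_sd: float = 0.1
    tree: ClusterTree = field(default_factory=ClusterTree)

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_src) < 1:
            raise DataValidationError("sizes must be positive")
        if self.n_src + max(self.target_sizes) > self.n_cells:
            raise DataValidationError("n_src + max(target_sizes) must not exceed n_cells")
        for name in ("dirichlet_concentration", "gamma_shape", "gamma_rate", "lfc_sd"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.cell_noise_sd < 0:
            raise DataValidationError("dispersion and noise sd must be nonnegative")
        lo, hi = self.de_fraction_range
        if not (0 < lo <= hi < 1):
            raise DataValidationError("de_fraction_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.lfc_up_probability <= 1.0:
            raise DataValidationError("lfc_up_probability must lie in [0, 1]")
        self.tree.validate()


@dataclass
class LabeledDataset:
    """A count matrix with ground-truth leaf labels (0-based)."""

    X: ExpressionMatrix
    y: np.ndarray
    top_node_of: dict[int, str]

    def __post_init__(self) -> None:
        self.y = validate_labels(self.y, n_cells=self.X.n_cells)

    @property
    def n_cells(self) -> int:
        return self.X.n_cells

    def top_nodes_present(self) -> set[str]:
        """Top-level node names realized by at least one cell."""
        return {self.top_node_of[label + 1] for label in np.unique(self.y)}


def sample_cluster_sizes(
    n_cells: int, n_leaves: int, concentration: float, seed
) -> np.ndarray:
    """Draw integer cluster sizes from a symmetric Dirichlet.

    Proportions are drawn from Dirichlet(concentration, ..., concentration)
    and converted to integers by largest-remainder rounding with a minimum
    of one cell per cluster; the sizes always sum exactly to *n_cells*.
    """
    if n_cells < n_leaves:
        raise DataValidationError("need at least one cell per cluster")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_leaves, float(concentration)))
    raw = p * n_cells
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for i in np.argsort(-remainder)[: n_cells - sizes.sum()]:
        sizes[i] += 1
    # enforce the one-cell minimum, taking from the largest clusters
    while (sizes < 1).any():
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1
    assert sizes.sum() == n_cells
    return sizes


def _perturb(background: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one round of differential expression to a background profile."""
    g = background.size
    lo, hi = cfg.de_fraction_range
    n_de = int(round(rng.uniform(lo, hi) * g))
    idx = rng.choice(g, size=n_de, replace=False)
    lfc = rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=n_de)
    # |log2 FC| is specified; the up/down split is calibrated so the median
    # library size matches the reference value of ~215 500 reads per cell
    sign = np.where(rng.random(n_de) < cfg.lfc_up_probability, 1.0, -1.0)
    profile = background.copy()
    profile[idx] = profile[idx] * np.exp2(sign * lfc)
    return profile


def _leaf_profiles(cfg: SimConfig, rng: np.random.Generator) -> dict[int, np.ndarray]:
    background = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_rate, size=cfg.n_genes)
    profiles: dict[int, np.ndarray] = {}

    def descend(node, bg: np.ndarray) -> None:
        prof = _perturb(bg, cfg, rng)
        if isinstance(node, int):
            profiles[node] = prof
        else:
            for child in node:
                descend(child, prof)

    for top in cfg.tree.spec:
        descend(top, background)
    return profiles


def generate_dataset(cfg: SimConfig, seed) -> LabeledDataset:
    """Generate one full labeled count dataset under the hierarchy.

    Deterministic for a fixed (cfg, seed) pair.
    """
    rng = np.random.default_rng(seed)
    tree = cfg.tree
    sizes = sample_cluster_sizes(
        cfg.n_cells, tree.n_leaves, cfg.dirichlet_concentration, rng
    )
    profiles = _leaf_profiles(cfg, rng)

    y = np.repeat(np.arange(tree.n_leaves), sizes)
    means = np.empty((cfg.n_genes, cfg.n_cells))
    for j, leaf in enumerate(tree.leaves):
        means[:, y == j] = profiles[leaf][:, None]

    if cfg.cell_noise_sd > 0:
        noise = rng.normal(0.0, cfg.cell_noise_sd, size=means.shape)
        means = np.maximum(means * (1.0 + noise), 0.0)

    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion  # variance = mu + dispersion * mu^2
        counts = rng.negative_binomial(r, r / (r + means))
    else:
        counts = rng.poisson(means)

    X = ExpressionMatrix(
        values=counts.astype(float),
        gene_ids=np.array([f"gene_{i:05d}" for i in range(cfg.n_genes)], dtype=object),
        cell_ids=np.array([f"cell_{i:05d}" for i in range(cfg.n_cells)], dtype=object),
        unit="counts",
    )
    return LabeledDataset(X=X, y=y, top_node_of=tree.top_node_of)


OVERLAP_MODES = ("complete", "incomplete", "none")


def split_source_target(
    d: LabeledDataset,
    mode: str,
    n_src: int,
    n_trg: int,
    seed,
    max_tries: int = 100,
    strict: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a dataset into disjoint source and target cell sets.

    ``complete``
        Both sides are random samples containing every top-level node.
    ``incomplete``
        Three randomly chosen top nodes are shared; of the remaining two,
        one is exclusive to the source and one to the target.
    ``none``
        Two top nodes form the target, the other three the source.

    The node assignment is re-randomized on every call (pass a fresh seed
    per repetition).  With ``strict=False`` the requested sizes are
    clamped to the number of eligible cells instead of raising (useful
    for the restrictive regimes, where the randomly drawn top nodes may
    hold fewer cells than asked for).
    """
    if mode not in OVERLAP_MODES:
        raise DataValidationError(f"unknown overlap mode {mode!r}")
    rng = np.random.default_rng(seed)
    top_names = list(dict.fromkeys(d.top_node_of.values()))
    cell_tops = np.array([d.top_node_of[label + 1] for label in d.y])

    for _ in range(max_tries):
        perm = rng.permutation(top_names)
        if mode == "complete":
            src_nodes = set(top_names)
            trg_nodes = set(top_names)
            if strict and n_src + n_trg > d.n_cells:
                raise DataValidationError("requested sizes exceed available cells")
            order = rng.permutation(d.n_cells)
            src_idx, trg_idx = order[:n_src], order[n_src : n_src + n_trg]
        else:
            if mode == "incomplete":
                shared = set(perm[:3])
                src_nodes = shared | {perm[3]}
                trg_nodes = shared | {perm[4]}
            else:  # none
                src_nodes = set(perm[:3])
                trg_nodes = set(perm[3:])
            src_pool = np.flatnonzero(np.isin(cell_tops, list(src_nodes)))
            trg_pool = np.flatnonzero(np.isin(cell_tops, list(trg_nodes)))
            if mode == "none":
                if strict and (n_src > src_pool.size or n_trg > trg_pool.size):
                    raise DataValidationError("requested sizes exceed eligible cells")
                src_idx = rng.choice(src_pool, size=min(n_src, src_pool.size), replace=False)
                trg_idx = rng.choice(trg_pool, size=min(n_trg, trg_pool.size), replace=False)
            else:
                if strict and n_src > src_pool.size:
                    raise DataValidationError("requested source size exceeds eligible cells")
                src_idx = rng.choice(src_pool, size=min(n_src, src_pool.size), replace=False)
                remaining = np.setdiff1d(trg_pool, src_idx)
                if strict and n_trg > remaining.size:
                    raise DataValidationError("requested target size exceeds eligible cells")
                trg_idx = rng.choice(remaining, size=min(n_trg, remaining.size), replace=False)

        src = _take(d, np.sort(src_idx))
        trg = _take(d, np.sort(trg_idx))
        if src.top_nodes_present() == src_nodes and trg.top_nodes_present() == trg_nodes:
            return src, trg
    raise DataValidationError(
        f"could not realize mode={mode!r} with every required top node present; "
        "sizes too small for the cluster structure"
    )


def _take(d: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        X=d.X.subset_cells(idx), y=d.y[idx].copy(), top_node_of=dict(d.top_node_of)
    )


def downsample(d: LabeledDataset, n: int, seed) -> LabeledDataset:
    """Uniform subsample of *n* cells without replacement, labels carried."""
    if n > d.n_cells:
        raise DataValidationError(f"cannot downsample {d.n_cells} cells to {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d.n_cells, size=n, replace=False))
    return _take(d, idx)
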