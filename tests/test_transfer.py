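"""End-to-end dictionary transfer and theta selection."""

import numpy as np
import pytest

from sctransfer import (
    DataValidationError,
    NMFConfig,
    SC3Config,
    TransferClusterModel,
    TransferConfig,
    adjusted_rand_index,
    binarize_assignments,
    fit_source_nmf,
    select_theta,
    target_cluster,
    transfer_cluster,
    transfer_weights,
)
from sctransfer.preprocess import log_transform
from sctransfer.simulate import SimConfig, generate_dataset, split_source_target


def _toy_pair(rng, n_src=30, n_trg=18, g=25, k=3):
    """Well-separated synthetic source/target sharing cluster structure."""
    protos = rng.random((g, k)) * 5 + 1
    y_src = np.repeat(np.arange(k), n_src // k)
    y_trg = np.repeat(np.arange(k), n_trg // k)
    X_src = protos[:, y_src] + rng.normal(0, 0.05, (g, n_src))
    X_trg = protos[:, y_trg] + rng.normal(0, 0.05, (g, n_trg))
    return np.abs(X_src), y_src, np.abs(X_trg), y_trg


def _wrap(make_matrix, values, ids=None):
    return make_matrix(values, gene_ids=ids)


class TestSelectTheta:
    def test_singleton_grid(self, make_matrix, rng):
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        pair = fit_source_nmf(X_src, y=y_src, cfg=NMFConfig(k=3, alpha=0.0))
        Wp = binarize_assignments(transfer_weights(X_trg, pair.H))
        cfg = TransferConfig(
            nmf=NMFConfig(k=3), sc3=SC3Config(k=3, seed=0), theta_grid=(0.3,)
        )
        theta, _, _, scores = select_theta(make_matrix(X_trg), pair.H, Wp, cfg)
        assert theta == 0.3
        assert set(scores) == {0.3}

    def test_scores_cover_grid(self, make_matrix, rng):
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        pair = fit_source_nmf(X_src, y=y_src, cfg=NMFConfig(k=3, alpha=0.0))
        Wp = binarize_assignments(transfer_weights(X_trg, pair.H))
        grid = (0.1, 0.4, 0.8)
        cfg = TransferConfig(
            nmf=NMFConfig(k=3), sc3=SC3Config(k=3, seed=0), theta_grid=grid
        )
        _, _, _, scores = select_theta(make_matrix(X_trg), pair.H, Wp, cfg)
        assert set(scores) == set(grid)

    def test_theta_zero_endpoint_equals_target_cluster_bitwise(self, make_matrix, rng):
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        pair = fit_source_nmf(X_src, y=y_src, cfg=NMFConfig(k=3, alpha=0.0))
        Wp = binarize_assignments(transfer_weights(X_trg, pair.H))
        sc3 = SC3Config(k=3, seed=77)
        cfg = TransferConfig(nmf=NMFConfig(k=3), sc3=sc3, theta_grid=(0.0,))
        _, _, labels, _ = select_theta(make_matrix(X_trg), pair.H, Wp, cfg)
        ref = target_cluster(make_matrix(X_trg), sc3)
        np.testing.assert_array_equal(labels, ref)

    def test_empty_grid_rejected(self):
        with pytest.raises(DataValidationError):
            TransferConfig(nmf=NMFConfig(k=2), sc3=SC3Config(k=2), theta_grid=())

    def test_duplicate_grid_rejected(self):
        with pytest.raises(DataValidationError):
            TransferConfig(nmf=NMFConfig(k=2), sc3=SC3Config(k=2), theta_grid=(0.2, 0.2))


class TestTransferCluster:
    def test_identical_source_target_recovers_labels_at_theta_one(
        self, make_matrix, rng
    ):
        X_src, y_src, _, _ = _toy_pair(rng, n_src=30, n_trg=30)

        def group_identical_columns(X):
            # at theta=1 the mixture has k distinct columns: group them
            _, labels = np.unique(X.values.round(9), axis=1, return_inverse=True)
            return labels

        cfg = TransferConfig(
            nmf=NMFConfig(k=3, alpha=0.0, seed=0),
            clusterer=group_identical_columns,
            theta_grid=(1.0,),
        )
        A = make_matrix(X_src)
        labels, theta, _ = transfer_cluster(A, y_src, A, cfg)
        assert theta == 1.0
        assert adjusted_rand_index(labels, y_src) == pytest.approx(1.0)

    def test_misaligned_gene_spaces_rejected(self, make_matrix, rng):
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        cfg = TransferConfig(nmf=NMFConfig(k=3), sc3=SC3Config(k=3))
        A = make_matrix(X_src)
        B = make_matrix(X_trg, gene_ids=[f"other{i}" for i in range(X_trg.shape[0])])
        with pytest.raises(DataValidationError):
            transfer_cluster(A, y_src, B, cfg)

    def test_absent_labels_generated_by_nmf(self, make_matrix, rng):
        X_src, y_src, X_trg, y_trg = _toy_pair(rng)
        cfg = TransferConfig(
            nmf=NMFConfig(k=3, alpha=0.0, seed=3),
            sc3=SC3Config(k=3, seed=3),
            theta_grid=(0.3, 0.6),
        )
        labels, _, diag = transfer_cluster(make_matrix(X_src), None, make_matrix(X_trg), cfg)
        assert len(labels) == X_trg.shape[1]
        # manufactured source labels recover the true source partition
        assert adjusted_rand_index(diag["y_src"], y_src) == pytest.approx(1.0)

    def test_end_to_end_seeded_determinism(self, make_matrix):
        sim = SimConfig(n_genes=300, n_cells=300, n_src=150, target_sizes=(80,))
        d = generate_dataset(sim, seed=21)
        src, trg = split_source_target(d, "complete", 150, 80, seed=22)
        Xs = log_transform(src.X)
        Xt = log_transform(trg.X)
        y = np.unique(src.y, return_inverse=True)[1]
        cfg = TransferConfig(
            nmf=NMFConfig(k=int(y.max()) + 1, max_iter=100, tol=1e-4, seed=5),
            sc3=SC3Config(k=len(np.unique(trg.y)), seed=5),
            theta_grid=(0.1, 0.5, 0.9),
        )
        out1 = transfer_cluster(Xs, y, Xt, cfg)
        out2 = transfer_cluster(Xs, y, Xt, cfg)
        np.testing.assert_array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]


class TestModelInterface:
    def test_fit_summary_and_tables(self, rng):
        import pandas as pd

        X_src, y_src, X_trg, y_trg = _toy_pair(rng)
        genes = [f"g{i}" for i in range(X_src.shape[0])]
        model = TransferClusterModel.from_dataframes(
            pd.DataFrame(X_trg, index=genes),
            pd.DataFrame(X_src, index=genes),
            y_src,
            theta_grid=(0.2, 0.6),
            seed=1,
        )
        res = model.fit()
        assert len(res.labels_) == X_trg.shape[1]
        assert res.theta_ in (0.2, 0.6)
        assert adjusted_rand_index(res.labels_, y_trg) == pytest.approx(1.0)
        tab = res.score_table()
        assert list(tab["theta"]) == [0.2, 0.6]
        assert tab["selected"].sum() == 1
        text = res.summary()
        assert "selected theta" in text
        assert f"{res.theta_:g}" in text

    def test_plot_kta_returns_axes(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        genes = [f"g{i}" for i in range(X_src.shape[0])]
        import pandas as pd

        model = TransferClusterModel.from_dataframes(
            pd.DataFrame(X_trg, index=genes),
            pd.DataFrame(X_src, index=genes),
            y_src,
            theta_grid=(0.2, 0.6),
        )
        ax = model.fit().plot_kta()
        assert ax.get_xlabel()

    def test_requires_dictionary_size_without_labels(self, make_matrix, rng):
        X_src, _, X_trg, _ = _toy_pair(rng)
        with pytest.raises(DataValidationError):
            TransferClusterModel(make_matrix(X_trg), make_matrix(X_src))

    def test_rejects_mismatched_gene_spaces(self, make_matrix, rng):
        X_src, y_src, X_trg, _ = _toy_pair(rng)
        B = make_matrix(X_src, gene_ids=[f"x{i}" for i in range(X_src.shape[0])])
        with pytest.raises(DataValidationError):
            TransferClusterModel(make_matrix(X_trg), B, y_src)
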