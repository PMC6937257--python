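import numpy as np
import pytest

from sctransfer import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_matrix():
    """Factory: wrap a 2-D array into an ExpressionMatrix with auto ids."""

    def _make(values, unit="counts", gene_ids=None, cell_ids=None):
        values = np.asarray(values, dtype=float)
        g, n = values.shape
        return ExpressionMatrix(
            values=values,
            gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)],
            cell_ids=cell_ids if cell_ids is not None else [f"c{j}" for j in range(n)],
            unit=unit,
        )

    return _make


@pytest.fixture
def two_blob_matrix(rng):
    """20 genes x 20 cells with two profile-distinct populations.

    The populations differ in which half of the genes they express, so
    Euclidean and correlation metrics all separate them.
    """
    profA = np.zeros(20)
    profA[:10] = 8.0
    profB = np.zeros(20)
    profB[10:] = 8.0
    X = np.hstack(
        [
            np.abs(profA[:, None] + rng.normal(0, 0.3, (20, 10))),
            np.abs(profB[:, None] + rng.normal(0, 0.3, (20, 10))),
        ]
    )
    truth = np.array([0] * 10 + [1] * 10)
    return X, truth
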