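import numpy as np
import pytest
import scipy.sparse as sp

from heartde.io_counts import CountMatrix, GroupLabels


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 cells, mixed zero pattern."""
    dense = np.array(
        [
            [5, 0, 2, 1],
            [0, 0, 0, 0],
            [1, 3, 0, 7],
        ]
    )
    return CountMatrix(dense, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def tiny_groups() -> GroupLabels:
    return GroupLabels(
        np.array([1, 1, 2, 2]), cell_ids=["c1", "c2", "c3", "c4"]
    )


def make_nb_counts(
    n_genes: int,
    n_cells: int,
    seed: int,
    mean_shape: float = 2.0,
    mean_offset: float = 0.5,
    nb_size: float = 2.0,
) -> CountMatrix:
    """Dense-ish NB counts where most genes are expressed in most cells.

    Used for calibration-style checks where the chi-square approximation of
    the combined statistic is within its domain (enough positive cells per
    gene).
    """
    rng = np.random.default_rng(seed)
    mu = rng.gamma(mean_shape, 1.0, n_genes) + mean_offset
    X = rng.negative_binomial(nb_size, nb_size / (nb_size + mu[:, None]), size=(n_genes, n_cells))
    return CountMatrix(
        sp.csr_matrix(X),
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
    )


@pytest.fixture
def nb_counts_medium() -> CountMatrix:
    return make_nb_counts(400, 300, seed=123)
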