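import numpy as np
import pytest
import scipy.sparse as sp

from cellgan.io import CountMatrix
from cellgan.preprocess import library_size_normalize
from cellgan.simulate import SyntheticSpec, generate_synthetic

PHI = 20000.0


@pytest.fixture(scope="session")
def small_dataset():
    """400 cells x 120 genes, 3 planted clusters with 10 markers each."""
    spec = SyntheticSpec(n_cells=400, n_genes=120, n_clusters=3,
                         marker_genes_per_cluster=10, marker_fold_change=8.0,
                         seed=7)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    matrix, labels, markers = small_dataset
    return library_size_normalize(matrix, PHI), labels, markers


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale study fixture: 3,000 cells x 200 genes, 3 clusters."""
    spec = SyntheticSpec(n_cells=3000, n_genes=200, n_clusters=3,
                         marker_genes_per_cluster=10, marker_fold_change=8.0,
                         seed=11)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def desk_normalized(desk_dataset):
    matrix, labels, markers = desk_dataset
    return library_size_normalize(matrix, PHI), labels, markers


def random_count_matrix(rng, n_cells=8, n_genes=6, density=0.4,
                        normalized_to=None):
    vals = sp.random(n_cells, n_genes, density=density, random_state=rng,
                     data_rvs=lambda n: rng.integers(1, 20, n).astype(float))
    vals = sp.csr_matrix(vals)
    if normalized_to is not None:
        # guarantee positive row sums so normalization is defined
        dense = np.asarray(vals.todense())
        zero_rows = np.flatnonzero(dense.sum(axis=1) == 0)
        dense[zero_rows, zero_rows % n_genes] = 1.0
        vals = sp.csr_matrix(dense)
    m = CountMatrix(sp.csr_matrix(vals),
                    [f"g{i}" for i in range(n_genes)],
                    [f"c{i}" for i in range(n_cells)])
    if normalized_to is not None:
        m = library_size_normalize(m, normalized_to)
    return m
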