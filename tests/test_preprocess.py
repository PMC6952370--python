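import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from cellgan.errors import (AlignmentError, DegenerateOutputError,
                            ParameterError)
from cellgan.io import CountMatrix
from cellgan.preprocess import (LabelVector, cluster_cells,
                                define_marker_genes, filter_cells_min_genes,
                                filter_genes_min_cells, fit_embedding,
                                library_size_normalize, transform_embedding)


def make_matrix(dense, normalized_to=None):
    dense = np.asarray(dense, dtype=float)
    return CountMatrix(sp.csr_matrix(dense),
                       [f"g{i}" for i in range(dense.shape[1])],
                       [f"c{i}" for i in range(dense.shape[0])],
                       normalized_to)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_gene_filter_drops_rare_genes():
    m = make_matrix([[1, 1, 0], [2, 1, 0], [3, 0, 0], [1, 0, 1]])
    out = filter_genes_min_cells(m, min_cells=3)
    assert out.gene_ids == ["g0"]
    assert out.cell_ids == m.cell_ids


def test_cell_filter_drops_shallow_cells():
    dense = np.zeros((3, 12))
    dense[0, :10] = 1   # exactly 10 expressed genes: kept
    dense[1, :9] = 1    # 9 expressed genes: dropped
    dense[2, :] = 1
    out = filter_cells_min_genes(make_matrix(dense), min_genes=10)
    assert out.cell_ids == ["c0", "c2"]


def test_filters_error_on_empty_result():
    with pytest.raises(DegenerateOutputError):
        filter_cells_min_genes(make_matrix(np.zeros((3, 5))), min_genes=1)
    with pytest.raises(DegenerateOutputError):
        filter_genes_min_cells(make_matrix(np.zeros((3, 5))), min_cells=1)


def test_filter_composition_reaches_fixed_point():
    rng = np.random.default_rng(5)
    dense = (rng.random((40, 30)) < 0.08).astype(float)
    dense[:, 0] = 1  # keep at least one gene/cell alive
    dense[0, :] = 1
    m = make_matrix(dense)
    for _ in range(5):
        before = (m.n_cells, m.n_genes)
        m = filter_cells_min_genes(filter_genes_min_cells(m, 3), 2)
        if (m.n_cells, m.n_genes) == before:
            break
    out = filter_cells_min_genes(filter_genes_min_cells(m, 3), 2)
    assert (out.n_cells, out.n_genes) == (m.n_cells, m.n_genes)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_preserves_proportions():
    out = library_size_normalize(make_matrix([[1, 1, 2]]), phi=20000)
    assert np.allclose(out.to_dense(), [[5000, 5000, 10000]])
    assert out.normalized_to == 20000


def test_normalize_row_sums_and_idempotence(small_dataset):
    m, _, _ = small_dataset
    once = library_size_normalize(m, 20000)
    sums = np.asarray(once.values.sum(axis=1)).ravel()
    assert np.allclose(sums, 20000, rtol=1e-6)
    twice = library_size_normalize(once, 20000)
    assert np.allclose(once.to_dense(), twice.to_dense(), rtol=1e-9)


def test_normalize_rejects_zero_cell():
    with pytest.raises(ParameterError, match="c1"):
        library_size_normalize(make_matrix([[1, 2], [0, 0]]))


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def test_embedding_matches_direct_eigendecomposition(small_normalized):
    """PC loadings agree with an eigendecomposition of the standardized HVG
    covariance computed independently."""
    m, _, _ = small_normalized
    emb = fit_embedding(m, n_hvg=60, n_pcs=10)
    # orthonormal basis
    gram = emb.pc_basis.T @ emb.pc_basis
    assert np.allclose(gram, np.eye(10), atol=1e-6)
    # explained variance non-increasing
    assert np.all(np.diff(emb.explained_variance) <= 1e-9)
    # oracle: eigendecomposition of the covariance of the standardized data
    X = np.log1p(np.asarray(m.values[:, emb.hvg_indices].todense()))
    Z = np.clip((X - emb.gene_means) / emb.gene_sds, -10, 10)
    Z = Z - Z.mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False))
    evals, evecs = evals[::-1], evecs[:, ::-1]
    assert np.allclose(emb.explained_variance, evals[:10], rtol=1e-6)
    for j in range(10):
        dot = abs(emb.pc_basis[:, j] @ evecs[:, j])
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_constant_gene_excluded_from_hvgs():
    rng = np.random.default_rng(0)
    dense = rng.poisson(3.0, size=(100, 30)).astype(float) + 1
    dense[:, 4] = 7.0  # constant gene in the (already normalized) matrix
    dense *= 20000 / dense.sum(axis=1, keepdims=True)
    dense[:, 4] = 7.0
    dense[:, 5] += 20000 - dense.sum(axis=1)  # restore exact row sums
    m = make_matrix(dense, normalized_to=20000.0)
    emb = fit_embedding(m, n_hvg=20, n_pcs=5)
    assert 4 not in set(emb.hvg_indices.tolist())


def test_hvg_equal_to_gene_count_is_identity_selection():
    rng = np.random.default_rng(1)
    dense = rng.poisson(2.0, size=(80, 25)).astype(float) + 1
    m = library_size_normalize(make_matrix(dense))
    emb = fit_embedding(m, n_hvg=25, n_pcs=5)
    assert sorted(emb.hvg_indices.tolist()) == list(range(25))


def test_transform_is_self_consistent_and_permutation_invariant(
        small_normalized):
    m, _, _ = small_normalized
    emb = fit_embedding(m, n_hvg=60, n_pcs=10)
    pcs = transform_embedding(emb, m)
    assert pcs.shape == (m.n_cells, 10)
    # permute gene columns (with ids): identical output
    rng = np.random.default_rng(2)
    perm = rng.permutation(m.n_genes)
    permuted = CountMatrix(m.values[:, perm],
                           [m.gene_ids[i] for i in perm], m.cell_ids,
                           m.normalized_to)
    assert np.allclose(transform_embedding(emb, permuted), pcs, atol=1e-9)


def test_fit_ignores_generated_cells_by_construction(small_normalized):
    """The frozen transform of real cells does not change when generated
    rows are appended *after* fitting — fitting touches real cells only."""
    m, _, _ = small_normalized
    emb = fit_embedding(m, n_hvg=60, n_pcs=10)
    fake = CountMatrix(m.values[:50], m.gene_ids,
                       [f"fake{i}" for i in range(50)], m.normalized_to)
    pcs_fake = transform_embedding(emb, fake)
    assert np.allclose(pcs_fake, transform_embedding(emb, m)[:50])


def test_transform_errors_on_missing_genes(small_normalized):
    m, _, _ = small_normalized
    emb = fit_embedding(m, n_hvg=60, n_pcs=10)
    truncated = CountMatrix(m.values[:, :50], m.gene_ids[:50], m.cell_ids)
    with pytest.raises(AlignmentError):
        transform_embedding(emb, truncated)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def blobs_50d(seed=0, n_per=150, k=3):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, 50)) * 12
    X = np.vstack([centers[i] + rng.standard_normal((n_per, 50))
                   for i in range(k)])
    y = np.repeat(np.arange(k), n_per)
    return X, y


@pytest.mark.parametrize("method", ["louvain", "kmeans"])
def test_clustering_recovers_separated_blobs(method):
    X, y = blobs_50d()
    labels = cluster_cells(X, method=method, resolution=0.15, k=3, seed=0)
    assert adjusted_rand_score(y, labels.labels) >= 0.99


def test_kmeans_single_blob_k1():
    rng = np.random.default_rng(0)
    labels = cluster_cells(rng.standard_normal((50, 5)), "kmeans", k=1,
                           seed=0)
    assert np.all(labels.labels == 0)


def test_louvain_is_deterministic_given_seed():
    X, _ = blobs_50d(seed=3)
    a = cluster_cells(X, "louvain", seed=42)
    b = cluster_cells(X, "louvain", seed=42)
    assert np.array_equal(a.labels, b.labels)


def test_unknown_method_rejected():
    with pytest.raises(ParameterError):
        cluster_cells(np.zeros((10, 2)), "spectral")


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def test_planted_markers_recovered(small_normalized):
    m, labels, markers = small_normalized
    counts = labels.class_counts()
    largest_two = np.argsort(-counts)[:2]
    found = define_marker_genes(m, labels, top_n=5, n_clusters=2)
    assert len(found.genes) == 10
    truth = set()
    for k in largest_two:
        truth |= {f"gene_{k * 10 + j}" for j in range(10)}
    assert set(found.genes) <= truth
    # per-cluster order preserved: first five from the largest cluster
    assert [c for c, _ in found.source_clusters[:5]] == \
        [int(largest_two[0])] * 5


def test_marker_ties_are_deterministic():
    dense = np.ones((40, 8))
    m = CountMatrix(sp.csr_matrix(dense), [f"g{i}" for i in range(8)],
                    [f"c{i}" for i in range(40)])
    labels = LabelVector(np.r_[np.zeros(25, int), np.ones(15, int)], 2)
    a = define_marker_genes(m, labels, top_n=3, n_clusters=2)
    b = define_marker_genes(m, labels, top_n=3, n_clusters=2)
    assert a.genes == b.genes


def test_marker_requires_enough_clusters(small_normalized):
    m, _, _ = small_normalized
    labels = LabelVector(np.zeros(m.n_cells, int), 1)
    with pytest.raises(ParameterError):
        define_marker_genes(m, labels, n_clusters=2)
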