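"""Count-matrix preprocessing: filtering, library-size normalization, the
frozen log/scale/HVG/PCA embedding, clustering, and marker-gene definition.

The embedding follows the Cell Ranger secondary-analysis recipe: library-size
normalization, natural log (as log1p — the matrices are dominated by zeros),
per-gene standardization, selection of the top highly variable genes by
binned normalized dispersion, and PCA on the standardized HVG submatrix. The
embedding is *fitted on real cells only* and then applied, frozen, to
generated cells; all downstream metrics live in that PC space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import (AlignmentError, DegenerateOutputError, ParameterError)
from .io import CountMatrix

STD_CLIP = 10.0  # clip standardized values, bounds outlier leverage


@dataclass
class LabelVector:
    """Integer cluster/cell-type label per cell."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= self.n_classes):
            raise ParameterError("labels must lie in [0, n_classes)")

    def __len__(self):
        return len(self.labels)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class EmbeddingModel:
    """Frozen preprocessing transform fitted on real cells.

    Stores the HVG choice, the per-gene standardization statistics on the
    log scale, and the PC loading matrix (hvg x n_pcs, columns orthonormal).
    """

    gene_ids: list[str]
    hvg_indices: np.ndarray          # column indices into gene_ids order
    gene_means: np.ndarray           # per-HVG mean of log1p values
    gene_sds: np.ndarray             # per-HVG sd of log1p values
    pc_basis: np.ndarray             # (n_hvg, n_pcs)
    explained_variance: np.ndarray   # per-PC variance of the training scores
    n_pcs: int
    log_applied: bool = True
    clip: float = STD_CLIP

    @property
    def hvg_gene_ids(self) -> list[str]:
        return [self.gene_ids[i] for i in self.hvg_indices]


@dataclass
class MarkerGeneSet:
    """Ordered marker genes with their (cluster, rank) provenance."""

    genes: list[str]
    source_clusters: list[tuple[int, int]]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("duplicate gene ids in marker set")


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_genes_min_cells(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes expressed (nonzero) in fewer than ``min_cells`` cells."""
    nnz_per_gene = np.asarray((m.values != 0).sum(axis=0)).ravel()
    keep = np.flatnonzero(nnz_per_gene >= min_cells)
    if keep.size == 0:
        raise DegenerateOutputError("gene filter removed every gene")
    return CountMatrix(sp.csr_matrix(m.values[:, keep]),
                       [m.gene_ids[i] for i in keep], m.cell_ids,
                       m.normalized_to)


def filter_cells_min_genes(m: CountMatrix, min_genes: int = 10) -> CountMatrix:
    """Drop cells with fewer than ``min_genes`` expressed genes."""
    nnz_per_cell = np.asarray((m.values != 0).sum(axis=1)).ravel()
    keep = np.flatnonzero(nnz_per_cell >= min_genes)
    if keep.size == 0:
        raise DegenerateOutputError("cell filter removed every cell")
    return m.subset_cells(keep)


def library_size_normalize(m: CountMatrix, phi: float = 20000.0) -> CountMatrix:
    """Rescale each cell to a total count of ``phi``."""
    if phi <= 0:
        raise ParameterError("phi must be positive")
    sums = np.asarray(m.values.sum(axis=1)).ravel()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ParameterError(
            f"cell(s) with zero total count, e.g. {m.cell_ids[zero[0]]!r}")
    scaled = sp.diags(phi / sums) @ m.values
    return CountMatrix(sp.csr_matrix(scaled), m.gene_ids, m.cell_ids, phi)


# ---------------------------------------------------------------------------
# HVG ranking (binned normalized dispersion, Cell Ranger style)
# ---------------------------------------------------------------------------

def hvg_ranking(values, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Rank genes by normalized dispersion and return the top ``n_top``
    column indices (descending dispersion; ties broken by column index).

    Dispersion is variance/mean of the (normalized, non-log) values; genes
    are binned into ``n_bins`` quantile bins of mean expression and the
    dispersion is robustly z-scored (median/MAD) within each bin. Genes with
    zero mean or zero variance rank last.
    """
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=0)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=0)).ravel()
    else:
        values = np.asarray(values)
        mean = values.mean(axis=0)
        sq = (values ** 2).mean(axis=0)
    var = np.maximum(sq - mean ** 2, 0.0)
    n_genes = mean.size
    if n_top > n_genes:
        raise ParameterError(f"n_top={n_top} exceeds gene count {n_genes}")
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    expressed = (mean > 0) & (var > 0)
    norm_disp = np.full(n_genes, -np.inf)
    if expressed.any():
        idx = np.flatnonzero(expressed)
        order = mean[idx].argsort(kind="stable")
        bins = np.array_split(idx[order], min(n_bins, idx.size))
        for b in bins:
            d = disp[b]
            med = np.median(d)
            mad = np.median(np.abs(d - med))
            norm_disp[b] = (d - med) / (1.4826 * mad + 1e-12)
    # stable sort on (-norm_disp, index): ties resolved by gene index
    ranked = np.lexsort((np.arange(n_genes), -norm_disp))
    return ranked[:n_top]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def fit_embedding(m: CountMatrix, n_hvg: int = 1000, n_pcs: int = 50,
                  clip: float = STD_CLIP) -> EmbeddingModel:
    """Fit the frozen log -> standardize -> HVG -> PCA transform."""
    if m.normalized_to is None:
        raise ParameterError("fit_embedding expects library-size normalized "
                             "counts (run library_size_normalize first)")
    n_expressed = int((np.asarray(m.values.sum(axis=0)).ravel() > 0).sum())
    if n_hvg > n_expressed:
        raise ParameterError(
            f"n_hvg={n_hvg} exceeds {n_expressed} expressed genes")
    if n_pcs > n_hvg:
        raise ParameterError("n_pcs cannot exceed n_hvg")
    hvg = np.sort(hvg_ranking(m.values, n_hvg))
    X = np.log1p(np.asarray(m.values[:, hvg].todense(), dtype=np.float64))
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = np.clip((X - means) / sds, -clip, clip)
    Z = Z - Z.mean(axis=0)  # clipping may reintroduce a small offset
    # economy SVD of the standardized HVG matrix; loadings = right vectors
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    basis = vt[:n_pcs].T.copy()
    # deterministic sign: largest-magnitude loading of each PC positive
    for j in range(basis.shape[1]):
        i = np.abs(basis[:, j]).argmax()
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    expl = (s[:n_pcs] ** 2) / max(m.n_cells - 1, 1)
    return EmbeddingModel(list(m.gene_ids), hvg, means, sds, basis, expl,
                          n_pcs, True, clip)


def transform_embedding(model: EmbeddingModel, m: CountMatrix) -> np.ndarray:
    """Project cells onto the fitted PC basis (alignment by gene id)."""
    wanted = model.hvg_gene_ids
    try:
        cols = m.gene_index(wanted)
    except ParameterError as e:
        raise AlignmentError(str(e)) from None
    X = np.asarray(m.values[:, cols].todense(), dtype=np.float64)
    if model.log_applied:
        X = np.log1p(X)
    Z = np.clip((X - model.gene_means) / model.gene_sds,
                -model.clip, model.clip)
    return Z @ model.pc_basis


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(pcs: np.ndarray, method: str = "louvain",
                  resolution: float = 0.15, k: int = 10,
                  seed: int = 0, n_neighbors: int = 15) -> LabelVector:
    """Cluster cells in PC space.

    ``louvain`` builds a symmetrized kNN graph (Euclidean, ``n_neighbors``)
    and runs Louvain modularity optimization at the given resolution;
    ``kmeans`` runs Lloyd iterations with ``k`` centroids. Labels are
    relabeled in decreasing cluster size so label 0 is the largest cluster.
    """
    pcs = np.asarray(pcs, dtype=np.float64)
    if not np.all(np.isfinite(pcs)):
        raise ParameterError("non-finite values in PC matrix")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, random_state=seed,
                        n_init=10).fit_predict(pcs)
    elif method == "louvain":
        import random as _random

        import igraph
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(
            n_neighbors=min(n_neighbors + 1, len(pcs))).fit(pcs)
        _, idx = nn.kneighbors(pcs)
        edges = {(min(i, j), max(i, j))
                 for i, row in enumerate(idx) for j in row[1:]}
        graph = igraph.Graph(n=len(pcs), edges=sorted(edges))
        igraph.set_random_number_generator(_random.Random(seed))
        labels = np.array(
            graph.community_multilevel(resolution=resolution).membership)
    else:
        raise ParameterError(f"unknown clustering method: {method!r}")
    # relabel by decreasing size (deterministic: ties by original label)
    counts = np.bincount(labels)
    order = np.lexsort((np.arange(counts.size), -counts))
    remap = np.empty(counts.size, dtype=np.int64)
    remap[order] = np.arange(counts.size)
    labels = remap[labels]
    return LabelVector(labels, int(labels.max()) + 1)


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def define_marker_genes(m: CountMatrix, labels: LabelVector, top_n: int = 5,
                        n_clusters: int = 2) -> MarkerGeneSet:
    """Top upregulated genes (one-vs-rest Welch t on log expression) for the
    ``n_clusters`` largest clusters; duplicates keep their first occurrence."""
    if labels.n_classes < n_clusters:
        raise ParameterError(
            f"need at least {n_clusters} clusters, have {labels.n_classes}")
    if top_n > m.n_genes:
        raise ParameterError("top_n exceeds gene count")
    X = np.log1p(np.asarray(m.values.todense(), dtype=np.float64))
    counts = labels.class_counts()
    largest = np.lexsort((np.arange(labels.n_classes), -counts))[:n_clusters]
    genes: list[str] = []
    source: list[tuple[int, int]] = []
    seen = set()
    for c in largest:
        in_c = labels.labels == c
        n1, n0 = int(in_c.sum()), int((~in_c).sum())
        if n1 < 2 or n0 < 2:
            raise ParameterError(f"cluster {c} too small for a t statistic")
        m1, m0 = X[in_c].mean(axis=0), X[~in_c].mean(axis=0)
        v1, v0 = X[in_c].var(axis=0, ddof=1), X[~in_c].var(axis=0, ddof=1)
        denom = np.sqrt(v1 / n1 + v0 / n0)
        t = np.where(denom > 0, (m1 - m0) / np.where(denom > 0, denom, 1.0),
                     0.0)
        ranked = np.lexsort((np.arange(m.n_genes), -t))
        rank = 0
        for g in ranked:
            if rank >= top_n:
                break
            gid = m.gene_ids[g]
            rank += 1
            if gid in seen:
                continue
            seen.add(gid)
            genes.append(gid)
            source.append((int(c), rank))
    return MarkerGeneSet(genes, source)
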