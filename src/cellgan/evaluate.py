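"""Generated-versus-real quality metrics.

All distribution-level comparisons run in the 50-PC space fitted on real
cells only (see :mod:`cellgan.preprocess`): the kernel MMD two-sample
statistic, the real-vs-fake random-forest AUC, the lightweight training
monitors, marker-gene Pearson correlation heat-map inputs, and a joint t-SNE
embedding for visualization.

The MMD kernel is a sum of three Gaussians, k(x, y) = sum_i exp(-||x-y||^2 /
sigma_i^2) with sigma_i in {m/2, m, 2m}, where m is the median over the
pooled sample of the average distance from a point to its 25 nearest
neighbors. The estimator is the biased V-statistic (self-terms included), so
mmd(X, X) is exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, ParameterError
from .io import CountMatrix
from .preprocess import MarkerGeneSet, hvg_ranking

MMD_KNN = 25


@dataclass
class EvaluationReport:
    mmd: float
    auc_mean: float
    auc_per_fold: list
    monitor: dict
    marker_correlation_real: np.ndarray | None = None
    marker_correlation_generated: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {"mmd": self.mmd, "auc_mean": self.auc_mean,
             "auc_per_fold": list(map(float, self.auc_per_fold)),
             "monitor": self.monitor}
        for key in ("marker_correlation_real", "marker_correlation_generated"):
            v = getattr(self, key)
            d[key] = None if v is None else np.asarray(v).tolist()
        return d


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------

def _mmd_bandwidth(pooled: np.ndarray) -> float:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=MMD_KNN + 1).fit(pooled)
    dists, _ = nn.kneighbors(pooled)
    return float(np.median(dists[:, 1:].mean(axis=1)))


def _kernel(sq_dists: np.ndarray, sigmas) -> np.ndarray:
    out = np.zeros_like(sq_dists)
    for s in sigmas:
        out += np.exp(-sq_dists / (s * s))
    return out


def mmd(a: np.ndarray, b: np.ndarray, bandwidth: float | None = None,
        unbiased: bool = False) -> float:
    """Squared-MMD estimate between two samples (rows = points).

    ``bandwidth`` overrides the pooled 25-NN median heuristic m; the kernel
    widths are then {m/2, m, 2m}. ``unbiased`` switches to the U-statistic
    (self-terms removed from the within-sample blocks).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ParameterError("samples must share dimensionality")
    if min(len(a), len(b)) < MMD_KNN + 1:
        raise ParameterError(
            f"need at least {MMD_KNN + 1} points per sample for the "
            "bandwidth heuristic")
    if bandwidth is None:
        bandwidth = _mmd_bandwidth(np.vstack([a, b]))
    sigmas = (bandwidth / 2.0, bandwidth, 2.0 * bandwidth)
    kaa = _kernel(cdist(a, a, "sqeuclidean"), sigmas)
    kbb = _kernel(cdist(b, b, "sqeuclidean"), sigmas)
    kab = _kernel(cdist(a, b, "sqeuclidean"), sigmas)
    n, m_ = len(a), len(b)
    if unbiased:
        np.fill_diagonal(kaa, 0.0)
        np.fill_diagonal(kbb, 0.0)
        term_a = kaa.sum() / (n * (n - 1))
        term_b = kbb.sum() / (m_ * (m_ - 1))
    else:
        term_a = kaa.mean()
        term_b = kbb.mean()
    return float(term_a + term_b - 2.0 * kab.mean())


def mmd_permutation_test(a: np.ndarray, b: np.ndarray, n_permutations: int =
                         200, seed: int = 0) -> tuple[float, np.ndarray]:
    """Observed MMD and its label-permutation null draws (shared bandwidth)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.vstack([a, b])
    bw = _mmd_bandwidth(pooled)
    sigmas = (bw / 2.0, bw, 2.0 * bw)
    K = _kernel(cdist(pooled, pooled, "sqeuclidean"), sigmas)
    n = len(a)

    def stat(idx_a, idx_b):
        return (K[np.ix_(idx_a, idx_a)].mean()
                + K[np.ix_(idx_b, idx_b)].mean()
                - 2.0 * K[np.ix_(idx_a, idx_b)].mean())

    observed = stat(np.arange(n), np.arange(n, len(pooled)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pooled))
        null[i] = stat(perm[:n], perm[n:])
    return float(observed), null


# ---------------------------------------------------------------------------
# real-vs-fake classification
# ---------------------------------------------------------------------------

def real_vs_fake_auc(real_pcs: np.ndarray, fake_pcs: np.ndarray,
                     seed: int = 0, n_trees: int = 1000,
                     n_folds: int = 5):
    """Five-fold cross-validated ROC AUC of a random forest separating real
    from generated cells in the shared PC space.

    1000 trees, Gini impurity, sqrt feature subsampling, grown until pure or
    leaves of < 2 samples; class sizes equalized by subsampling the larger.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    real_pcs = np.asarray(real_pcs, float)
    fake_pcs = np.asarray(fake_pcs, float)
    rng = np.random.default_rng(seed)
    n = min(len(real_pcs), len(fake_pcs))
    if n < n_folds:
        raise ParameterError("class size smaller than the fold count")
    if len(real_pcs) > n:
        real_pcs = real_pcs[rng.choice(len(real_pcs), n, replace=False)]
    if len(fake_pcs) > n:
        fake_pcs = fake_pcs[rng.choice(len(fake_pcs), n, replace=False)]
    X = np.vstack([real_pcs, fake_pcs])
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", max_features="sqrt",
            min_samples_leaf=1, random_state=seed, n_jobs=1)
        rf.fit(X[train_idx], y[train_idx])
        prob = rf.predict_proba(X[test_idx])[:, 1]
        aucs.append(roc_auc_score(y[test_idx], prob))
    return float(np.mean(aucs)), [float(a) for a in aucs]


# ---------------------------------------------------------------------------
# training monitors
# ---------------------------------------------------------------------------

def _sparsity(values) -> float:
    nnz = (values != 0).sum()
    return float(1.0 - nnz / (values.shape[0] * values.shape[1]))


def training_monitors(real_test: CountMatrix, generated: CountMatrix,
                      n_hvg: int = 1000) -> dict:
    """Mean-expression distance, per-matrix sparsity, and HVG-set overlap."""
    if generated.gene_ids != real_test.gene_ids:
        try:
            cols = generated.gene_index(real_test.gene_ids)
        except ParameterError as e:
            raise AlignmentError(str(e)) from None
        gen_vals = generated.values[:, cols]
    else:
        gen_vals = generated.values
    n_hvg = min(n_hvg, real_test.n_genes)
    mean_real = np.asarray(real_test.values.mean(axis=0)).ravel()
    mean_gen = np.asarray(gen_vals.mean(axis=0)).ravel()
    hvg_real = set(hvg_ranking(real_test.values, n_hvg).tolist())
    hvg_gen = set(hvg_ranking(gen_vals, n_hvg).tolist())
    return {
        "mean_expr_distance": float(np.linalg.norm(mean_real - mean_gen)),
        "mean_sparsity_real": _sparsity(real_test.values),
        "mean_sparsity_generated": _sparsity(gen_vals),
        "hvg_intersection": len(hvg_real & hvg_gen),
    }


# ---------------------------------------------------------------------------
# marker correlation
# ---------------------------------------------------------------------------

def marker_correlation(m: CountMatrix, markers: MarkerGeneSet) -> np.ndarray:
    """Pairwise Pearson correlation of log-scale marker expression."""
    cols = m.gene_index(markers.genes)
    X = np.log1p(np.asarray(m.values[:, cols].todense(), dtype=np.float64))
    sds = X.std(axis=0)
    constant = sds <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant marker gene(s); their "
            "correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# joint visualization embedding
# ---------------------------------------------------------------------------

def embed_for_visualization(real_pcs: np.ndarray, fake_pcs: np.ndarray,
                            seed: int = 0):
    """Joint 2-D t-SNE of real and generated cells; returns (coords,
    is_real) with provenance preserved."""
    from sklearn.manifold import TSNE

    real_pcs = np.asarray(real_pcs, float)
    fake_pcs = np.asarray(fake_pcs, float)
    X = np.vstack([real_pcs, fake_pcs])
    perplexity = min(30.0, max(2.0, (len(X) - 1) / 3.0))
    coords = TSNE(n_components=2, random_state=seed, init="pca",
                  perplexity=perplexity).fit_transform(X)
    is_real = np.r_[np.ones(len(real_pcs), bool),
                    np.zeros(len(fake_pcs), bool)]
    return coords, is_real


# ---------------------------------------------------------------------------
# one-call report
# ---------------------------------------------------------------------------

def evaluate_generated(real_test: CountMatrix, generated: CountMatrix,
                       embedding, markers: MarkerGeneSet | None = None,
                       seed: int = 0, n_trees: int = 1000) -> EvaluationReport:
    """Full evaluation of one generated-vs-real comparison.

    ``embedding`` must have been fitted on real cells only; both matrices are
    projected with it (never refitted).
    """
    from .preprocess import transform_embedding

    real_pcs = transform_embedding(embedding, real_test)
    fake_pcs = transform_embedding(embedding, generated)
    mmd_value = mmd(real_pcs, fake_pcs)
    auc_mean, auc_folds = real_vs_fake_auc(real_pcs, fake_pcs, seed=seed,
                                           n_trees=n_trees)
    monitor = training_monitors(real_test, generated,
                                n_hvg=min(1000, real_test.n_genes))
    corr_real = corr_gen = None
    if markers is not None:
        corr_real = marker_correlation(real_test, markers)
        corr_gen = marker_correlation(generated, markers)
    return EvaluationReport(mmd_value, auc_mean, auc_folds, monitor,
                            corr_real, corr_gen)
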