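"""Downsampling -> augmentation -> classification experiment.

One cluster is artificially shrunk (nested, seeded subsets at a grid of
fractions), and three random-forest training regimes are compared on
held-out test cells:

* ``downsampled`` — the kept target cells plus 70% of the other clusters;
* ``upsampled``  — downsampled plus copies drawn with replacement from the
  kept cells;
* ``augmented``  — downsampled plus generator-produced target-cluster cells.

Classifiers run on the frozen PC embedding fitted on the (downsampled) real
training cells; F1 of the target class on the test set is reported per
(level, seed, regime). Test cells are disjoint from every classifier
training set and from the cells any generator was trained on — asserted,
not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import IntegrityError, ParameterError
from .io import CountMatrix
from .preprocess import LabelVector, fit_embedding, transform_embedding

DEFAULT_LEVELS = (0.50, 0.25, 0.10, 0.05, 0.03, 0.02, 0.01, 0.005)


@dataclass
class DownsampleSpec:
    target_cluster: int
    levels: tuple = DEFAULT_LEVELS
    seeds: tuple = (0, 1, 2, 3, 4)
    nested: bool = True
    rounding: str = "half_up"

    def __post_init__(self):
        lv = tuple(self.levels)
        if not lv or any(not (0 < x <= 1) for x in lv) \
                or any(a <= b for a, b in zip(lv, lv[1:])):
            raise ParameterError(
                "levels must be strictly decreasing fractions in (0, 1]")
        if not self.seeds:
            raise ParameterError("at least one seed is required")
        if self.rounding not in ("half_up", "floor", "ceil"):
            raise ParameterError(f"unknown rounding rule: {self.rounding!r}")
        self.levels = lv


def _round_count(level: float, size: int, rounding: str) -> int:
    x = level * size
    if rounding == "half_up":
        return int(np.floor(x + 0.5))
    return int(np.floor(x)) if rounding == "floor" else int(np.ceil(x))


def downsample_cluster(labels: LabelVector, spec: DownsampleSpec,
                       level: float, seed: int) -> np.ndarray:
    """Uniform subset of the target cluster at ``level``; for a fixed seed
    smaller levels are prefixes of (hence subsets of) larger ones."""
    members = np.flatnonzero(labels.labels == spec.target_cluster)
    if members.size == 0:
        raise ParameterError(f"cluster {spec.target_cluster} is empty")
    k = _round_count(level, members.size, spec.rounding)
    if k == 0:
        raise ParameterError(
            f"level {level} of {members.size} cells rounds to zero")
    perm = np.random.default_rng(seed).permutation(members)
    return np.sort(perm[:k])


# ---------------------------------------------------------------------------
# training/test set construction
# ---------------------------------------------------------------------------

def _stratified_split(labels: LabelVector, exclude_cluster: int,
                      train_frac: float, rng: np.random.Generator):
    """Per-cluster train/test split of all clusters except the target."""
    train, test = [], []
    for c in range(labels.n_classes):
        if c == exclude_cluster:
            continue
        members = np.flatnonzero(labels.labels == c)
        perm = rng.permutation(members)
        cut = int(round(train_frac * members.size))
        train.append(perm[:cut])
        test.append(perm[cut:])
    return (np.sort(np.concatenate(train)) if train else np.array([], int),
            np.sort(np.concatenate(test)) if test else np.array([], int))


def build_training_sets(data: CountMatrix, labels: LabelVector,
                        kept: np.ndarray, generated: CountMatrix | None,
                        target_cluster: int, upsample_to: int = 5000,
                        train_frac: float = 0.7, seed: int = 0,
                        test_idx: np.ndarray | None = None,
                        rest_cluster: int | None = None,
                        gan_training_cells: np.ndarray | None = None):
    """Index sets for the three regimes plus the held-out test set.

    Target-cluster test cells are drawn from cells outside ``kept`` (and
    outside ``gan_training_cells`` if given), mirroring the requirement that
    test cells were seen by no trained generator. Returns a dict with keys
    ``downsampled``/``upsampled`` (index arrays into ``data``, repeats
    allowed), ``augmented_generated`` (the generated matrix or None) and
    ``test_idx``.
    """
    kept = np.asarray(kept, dtype=np.intp)
    if not np.all(labels.labels[kept] == target_cluster):
        raise ParameterError("kept indices must all belong to the target "
                             "cluster")
    rng = np.random.default_rng(seed)
    members = np.flatnonzero(labels.labels == target_cluster)
    if test_idx is None:
        other_train, other_test = _stratified_split(
            labels, target_cluster, train_frac, rng)
        forbidden = set(kept.tolist())
        if gan_training_cells is not None:
            forbidden |= set(np.asarray(gan_training_cells).tolist())
        pool = np.array([i for i in members if i not in forbidden], dtype=np.intp)
        n_test = _round_count(1.0 - train_frac, members.size, "half_up")
        if pool.size < n_test:
            raise ParameterError(
                "not enough unseen target cells for the test split")
        target_test = np.sort(rng.choice(pool, n_test, replace=False))
        test_idx = np.sort(np.concatenate([target_test, other_test]))
    else:
        test_idx = np.asarray(test_idx, dtype=np.intp)
        mask = np.ones(data.n_cells, dtype=bool)
        mask[test_idx] = False
        other = (labels.labels != target_cluster) & mask
        if rest_cluster is not None:
            other &= labels.labels == rest_cluster
        other_train = np.flatnonzero(other)
    if rest_cluster is not None:
        other_train = other_train[labels.labels[other_train] == rest_cluster]
        test_keep = (labels.labels[test_idx] == target_cluster) \
            | (labels.labels[test_idx] == rest_cluster)
        test_idx = test_idx[test_keep]

    down = np.concatenate([kept, other_train])
    ups = np.concatenate(
        [down, rng.choice(kept, size=upsample_to, replace=True)])

    sets = {"downsampled": np.sort(down), "upsampled": np.sort(ups),
            "augmented_generated": generated, "test_idx": test_idx,
            "other_train": np.sort(other_train), "kept": kept}
    _assert_no_leakage(sets, gan_training_cells)
    return sets


def _assert_no_leakage(sets, gan_training_cells=None):
    test = set(sets["test_idx"].tolist())
    for key in ("downsampled", "upsampled"):
        overlap = test & set(sets[key].tolist())
        if overlap:
            raise IntegrityError(
                f"test cells leak into the {key} training set: "
                f"{sorted(overlap)[:5]} ...")
    if gan_training_cells is not None:
        overlap = test & set(np.asarray(gan_training_cells).tolist())
        if overlap:
            raise IntegrityError(
                f"test cells were seen by the generator: "
                f"{sorted(overlap)[:5]} ...")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def subpopulation_f1(train_X: np.ndarray, train_y: np.ndarray,
                     test_X: np.ndarray, test_y: np.ndarray,
                     seed: int = 0, n_trees: int = 1000,
                     class_weight: str = "balanced_subsample") -> float:
    """F1 of the target class from a class-weighted 1000-tree random forest
    on PC features (binary: target cluster vs rest).

    Class weights are inversely proportional to class frequencies, applied
    per bootstrap sample (``balanced_subsample``): with globally balanced
    weights, duplicating minority cells is a near no-op (the reweighting
    cancels the duplication), which would make the upsampling baseline
    meaningless at small scale.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import f1_score

    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ParameterError("training set contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        class_weight=class_weight, random_state=seed, n_jobs=1)
    rf.fit(np.asarray(train_X, float), train_y)
    pred = rf.predict(np.asarray(test_X, float))
    return float(f1_score(np.asarray(test_y, int), pred, pos_label=1))


# ---------------------------------------------------------------------------
# generator factories
# ---------------------------------------------------------------------------

def oracle_gan_factory(phi: float = 20000.0):
    """Factory producing the resampling oracle: a stand-in generator drawing
    from the empirical distribution of the non-test target-cluster cells.
    Used to test the experiment logic without adversarial training."""
    from .simulate import oracle_generator

    def factory(data, labels, context):
        pool = context["target_pool"]

        def gen_fn(n, seed):
            sub = data.subset_cells(pool)
            sub_labels = LabelVector(np.zeros(len(pool), dtype=int), 1)
            return oracle_generator(sub, sub_labels, 0, n, seed=seed,
                                    phi=int(phi))

        return gen_fn, pool

    return factory


def conditional_gan_factory(gspec_builder, cspec_builder, cfg_builder):
    """Factory that trains a real conditional GAN on the downsampled
    training cells (kept target cells plus the other-cluster training
    cells), conditioned on target-vs-rest."""
    from .conditional import generate_class, train_conditional

    def factory(data, labels, context):
        train_idx = np.sort(np.concatenate(
            [context["kept"], context["other_train"]]))
        sub = data.subset_cells(train_idx)
        y = (labels.labels[train_idx] == context["target_cluster"]).astype(int)
        state = train_conditional(
            sub, LabelVector(y, 2), gspec_builder(sub.n_genes),
            cspec_builder(sub.n_genes), cfg_builder(context["seed"]))

        def gen_fn(n, seed):
            return generate_class(state, 1, n, seed=seed)

        return gen_fn, train_idx

    return factory


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def run_grid(data: CountMatrix, labels: LabelVector, spec: DownsampleSpec,
             gan_factory, augmentation_sizes=(5000,), n_pcs: int = 50,
             n_hvg: int | None = None, n_trees: int = 1000,
             train_frac: float = 0.7, rest_cluster: int | None = None,
             upsample_to: int = 5000) -> pd.DataFrame:
    """Full (level x seed x regime) sweep; returns a long-format frame with
    columns level, seed, regime, augmentation_size, n_kept, f1."""
    if data.normalized_to is None:
        raise ParameterError("run_grid expects library-size normalized data")
    members = np.flatnonzero(labels.labels == spec.target_cluster)
    n_hvg = min(n_hvg or 1000, data.n_genes)
    rows = []
    for seed in spec.seeds:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 9173)))
        perm = np.random.default_rng(seed).permutation(members)
        n_max = _round_count(max(spec.levels), members.size, spec.rounding)
        other_train, other_test = _stratified_split(
            labels, spec.target_cluster, train_frac, rng)
        if rest_cluster is not None:
            other_train = other_train[
                labels.labels[other_train] == rest_cluster]
            other_test = other_test[labels.labels[other_test] == rest_cluster]
        # target test cells: unseen by any generator at any level
        unseen = perm[n_max:]
        n_test = _round_count(1 - train_frac, members.size, "half_up")
        if unseen.size < n_test:
            raise ParameterError("max level leaves too few unseen target "
                                 "cells for the test split")
        target_test = np.sort(rng.choice(unseen, n_test, replace=False))
        test_idx = np.sort(np.concatenate([target_test, other_test]))
        target_pool = np.sort(np.array(
            [i for i in members if i not in set(target_test.tolist())],
            dtype=np.intp))

        for level in spec.levels:
            k = _round_count(level, members.size, spec.rounding)
            if k == 0:
                raise ParameterError(f"level {level} rounds to zero cells")
            kept = np.sort(perm[:k])
            context = {"kept": kept, "other_train": other_train,
                       "target_pool": target_pool, "test_idx": test_idx,
                       "target_cluster": spec.target_cluster, "seed": seed,
                       "phi": data.normalized_to}
            gen_fn, gan_cells = gan_factory(data, labels, context)
            if set(test_idx.tolist()) & set(np.asarray(gan_cells).tolist()):
                raise IntegrityError("generator saw test cells")
            generated = gen_fn(max(augmentation_sizes), seed)

            sets = build_training_sets(
                data, labels, kept, generated, spec.target_cluster,
                upsample_to=upsample_to, train_frac=train_frac, seed=seed,
                test_idx=test_idx, rest_cluster=rest_cluster,
                gan_training_cells=gan_cells)
            train_real = sets["downsampled"]
            emb = fit_embedding(data.subset_cells(np.unique(train_real)),
                                n_hvg=n_hvg, n_pcs=min(n_pcs, n_hvg))
            pcs_all = transform_embedding(emb, data)
            gen_pcs = transform_embedding(emb, generated)
            test_X = pcs_all[sets["test_idx"]]
            test_y = (labels.labels[sets["test_idx"]]
                      == spec.target_cluster).astype(int)

            def f1_of(idx, extra_X=None):
                X = pcs_all[idx]
                y = (labels.labels[idx] == spec.target_cluster).astype(int)
                if extra_X is not None:
                    X = np.vstack([X, extra_X])
                    y = np.r_[y, np.ones(len(extra_X), dtype=int)]
                return subpopulation_f1(X, y, test_X, test_y, seed=seed,
                                        n_trees=n_trees)

            rows.append((level, seed, "downsampled", 0, k,
                         f1_of(sets["downsampled"])))
            rows.append((level, seed, "upsampled", upsample_to, k,
                         f1_of(sets["upsampled"])))
            for size in augmentation_sizes:
                rows.append((level, seed, "augmented", size, k,
                             f1_of(sets["downsampled"], gen_pcs[:size])))
    return pd.DataFrame(rows, columns=["level", "seed", "regime",
                                       "augmentation_size", "n_kept", "f1"])
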