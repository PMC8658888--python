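"""Data splitting and model evaluation.

Splitters: seeded random k-fold, grouped k-fold (groups — e.g. isomer
pairs — never span folds), and a k-means cluster split that assigns whole
clusters to the test side so the test set stays inside the model's
applicability domain.  Metrics: ROC-AUC for classification and the
coefficient of determination r^2 for regression, aggregated over folds as
mean +/- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .data_io import EvalReport, LatentMatrix, QSARDataset, Task
from .errors import ConfigurationError, MetricUndefinedError

DEFAULT_K = 5


@dataclass
class FoldSplit:
    """k disjoint, exhaustive test folds over indices 0..n-1."""

    test_folds: list  # list of index arrays
    n: int

    @property
    def k(self) -> int:
        return len(self.test_folds)

    def train_fold(self, i: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.test_folds[i]] = False
        return np.flatnonzero(mask)

    def __iter__(self):
        for i in range(self.k):
            yield self.train_fold(i), np.asarray(self.test_folds[i])


def kfold(n: int, k: int = DEFAULT_K, seed: int = 0, groups=None) -> FoldSplit:
    """Seeded k-fold split; with `groups`, whole groups stay in one fold."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if groups is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(np.zeros(n))]
        return FoldSplit(test_folds=folds, n=n)
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("groups must have length n")
    unique = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    if len(unique) < k:
        raise ValueError(f"need at least {k} groups for {k} folds")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    fold_members: list = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    group_idx = {g: np.flatnonzero(groups == g) for g in unique}
    # greedy balance: each group goes to the currently smallest fold
    for g in sorted(order, key=lambda g: -len(group_idx[g])):
        i = int(sizes.argmin())
        fold_members[i].append(g)
        sizes[i] += len(group_idx[g])
    folds = [np.sort(np.concatenate([group_idx[g] for g in members]))
             for members in fold_members]
    return FoldSplit(test_folds=folds, n=n)


def cluster_split(latents: LatentMatrix, train_frac: float = 0.8, seed: int = 0,
                  n_clusters: int | None = None):
    """k-means split assigning whole clusters to the test side.

    Clusters are visited in seeded random order and moved to the test side
    until the test target (round(n * (1 - train_frac))) is reached, so the
    target is exceeded by at most part of one cluster.  Default cluster
    count max(5, round(n/10)) keeps clusters small enough for the target
    fraction to be achievable.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    X = latents.values
    n = X.shape[0]
    if n < 10:
        raise ValueError("cluster_split requires n >= 10")
    target_test = round(n * (1.0 - train_frac))
    if target_test < 1 or target_test > n - 1:
        raise ValueError(
            f"train_frac={train_frac} leaves no test (or no train) points at n={n}")
    if n_clusters is None:
        n_clusters = max(5, round(n / 10))
    n_clusters = min(n_clusters, n)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assignment = km.fit_predict(X)
    rng = np.random.default_rng(seed)
    members = {c: np.flatnonzero(assignment == c) for c in range(n_clusters)}
    order = list(rng.permutation(n_clusters))
    sizes = [len(members[c]) for c in order]
    # subset-sum DP: largest achievable test size not exceeding the target
    reach = {0: []}
    for pos, size in enumerate(sizes):
        for total, subset in list(reach.items()):
            new = total + size
            if new <= target_test and new not in reach:
                reach[new] = subset + [pos]
    best_total = max(reach)
    chosen = list(reach[best_total])
    if best_total < target_test:
        # exceed the target by one extra cluster only if that lands closer
        candidates = [p for p in range(len(sizes)) if p not in set(chosen)]
        extra = min(candidates,
                    key=lambda p: abs(best_total + sizes[p] - target_test),
                    default=None)
        if extra is not None and \
                abs(best_total + sizes[extra] - target_test) < target_test - best_total:
            chosen.append(extra)
    test_idx: list = []
    for pos in chosen:
        test_idx.extend(members[order[pos]].tolist())
    test = np.sort(np.asarray(test_idx, dtype=int))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    train = np.flatnonzero(mask)
    if len(train) == 0:
        raise ValueError("cluster split left no training points; lower n_clusters")
    return train, test


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve = P(score+ > score-) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise MetricUndefinedError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y, s))


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise MetricUndefinedError("r^2 needs at least 2 points")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise MetricUndefinedError("r^2 undefined for zero label variance")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def task_metric(task: Task) -> str:
    return "roc_auc" if Task(task) is Task.classification else "r2"


def score_predictions(task: Task, y_true, scores) -> float:
    if Task(task) is Task.classification:
        return roc_auc(y_true, scores)
    return r_squared(y_true, scores)


def cross_validate(dataset: QSARDataset, model_recipe: str, k: int = DEFAULT_K,
                   augment: bool = False, seed: int = 0,
                   encoder_spec=None, config=None, n_extra: int = 9,
                   trainer_kwargs: dict | None = None) -> EvalReport:
    """k-fold cross-validation of one model recipe on a SMILES dataset.

    Recipes: ``crnn`` / ``cnn`` / ``augcrnn`` (CRNN with train-fold
    SMILES-enumeration augmentation) / ``svm`` (on latent vectors) /
    ``rf`` (on circular fingerprints).  Augmentation expands only the
    training folds; test folds stay canonical.
    """
    from . import baselines, training
    from .crnn_model import (CRNNConfig, build_cnn, build_crnn, clone_config,
                             predict_scores)
    from .encoder import EncoderSpec, encode
    from .smiles_aug import augment_training_set, canonicalize

    if model_recipe not in {"crnn", "cnn", "augcrnn", "svm", "rf"}:
        raise ConfigurationError(f"unknown model recipe {model_recipe!r}")
    if augment and model_recipe in {"cnn", "svm", "rf"}:
        raise ConfigurationError(f"augmentation is not defined for {model_recipe!r}")
    augment = augment or model_recipe == "augcrnn"
    if encoder_spec is None:
        encoder_spec = EncoderSpec()
    trainer_kwargs = dict(trainer_kwargs or {})
    split = kfold(len(dataset), k=k, seed=seed, groups=dataset.groups)
    canonical = [canonicalize(s) for s in dataset.smiles]
    y = dataset.y
    fold_scores = []
    for fold_i, (train_idx, test_idx) in enumerate(split):
        fold_seed = seed * 10_000 + fold_i
        test_X = encode(encoder_spec, [canonical[i] for i in test_idx]).values
        test_y = y[test_idx]
        if model_recipe == "rf":
            fps = np.stack([baselines.ecfp(s) for s in canonical])
            model = baselines.fit_rf(fps[train_idx], y[train_idx], dataset.task,
                                     seed=fold_seed)
            scores = baselines.predict_scores_sklearn(model, fps[test_idx], dataset.task)
        elif model_recipe == "svm":
            lat = encode(encoder_spec, canonical).values
            model = baselines.fit_svm(lat[train_idx], y[train_idx], dataset.task,
                                      seed=fold_seed)
            scores = baselines.predict_scores_sklearn(model, lat[test_idx], dataset.task)
        else:
            if augment:
                aug = augment_training_set(dataset.subset(train_idx),
                                           n_extra=n_extra, seed=fold_seed)
                train_X = encode(encoder_spec, aug.smiles).values
                train_y = np.asarray(aug.labels, dtype=float)
            else:
                train_X = encode(encoder_spec, [canonical[i] for i in train_idx]).values
                train_y = y[train_idx]
            cfg = config if config is not None else CRNNConfig()
            cfg = clone_config(cfg, task=dataset.task, latent_dim=encoder_spec.latent_dim)
            if model_recipe == "cnn":
                state = build_cnn(cfg, seed=fold_seed)
                state, _ = training.train_single_phase_run(
                    state, (train_X, train_y), (test_X, test_y), cfg, **trainer_kwargs)
            else:
                state = build_crnn(cfg, seed=fold_seed)
                state, _ = training.train_three_phase(
                    state, (train_X, train_y), (test_X, test_y), cfg, **trainer_kwargs)
            scores = predict_scores(state, test_X)
        fold_scores.append(score_predictions(dataset.task, test_y, scores))
    return EvalReport(per_fold=fold_scores, metric=task_metric(dataset.task))
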