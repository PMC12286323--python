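"""Splitting, k-NN classification, and channel-combination search.

The classifier is plain k-NN with Euclidean distance and majority vote.
Determinism rules (needed for reproducible combo rankings): distance
ties keep training-point insertion order; vote ties go to the tied class
with the smaller summed neighbor distance, then to the earlier class in
sorted order (which places ``not_understood`` — the negative class —
before ``understood``).  The per-query score is the fraction of the k
neighbors in the positive class and feeds the ROC/AUC.

Channel search enumerates every combination of up to ``max_size``
channels (6195 for 20 channels, sizes 1-4), re-tunes k per combination
on the training split, and ranks combinations by test accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .labeling import NOT_UNDERSTOOD, UNDERSTOOD


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint stratified train/test trial-id sets."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int
    fractions: tuple[float, float] = (0.70, 0.30)


def make_split(
    labeled: Sequence, seed: int, train_frac: float = 0.70
) -> SplitPlan:
    """Stratified random 70/30 split at trial level.

    Per class, round(n * train_frac) trials go to training (matching the
    study's printed marginals, e.g. 174/74 and 141/61 for strategy 1).
    Augmented window instances derived from one trial must all follow
    that trial's side, which holds automatically because the split is by
    trial id.
    """
    by_class: dict[str, list[str]] = {}
    for item in labeled:
        by_class.setdefault(item.label, []).append(item.trial_id)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in sorted(by_class):
        ids = by_class[label]
        if len(ids) < 2:
            raise SplitError(f"class {label!r} has {len(ids)} trial(s); need >= 2")
        n_train = int(len(ids) * train_frac + 0.5)
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitPlan(frozenset(train), frozenset(test), seed, (train_frac, 1 - train_frac))


@dataclass
class KnnModel:
    """Fitted k-NN: training matrix, integer labels, class names."""

    k: int
    X: np.ndarray
    y: np.ndarray  # int codes into classes
    classes: tuple[str, ...]
    positive: Optional[str] = UNDERSTOOD

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.X.shape[0]):
            raise ValueError(
                f"k={self.k} outside [1, n_train={self.X.shape[0]}]"
            )


def fit_knn(
    X: np.ndarray,
    labels: Sequence[str],
    k: int,
    positive: Optional[str] = UNDERSTOOD,
) -> KnnModel:
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels)))
    y = np.array([classes.index(l) for l in labels])
    return KnnModel(k, np.asarray(X, dtype=float), y, classes, positive)


def _predict_from_sorted(
    nb_y: np.ndarray, nb_d: np.ndarray, k: int, n_classes: int
) -> np.ndarray:
    """Majority vote over the first k sorted neighbors of each query row.

    Vote ties resolve to the tied class with the smallest summed
    neighbor distance, then to the smallest class index.
    """
    oh = nb_y[:, :k, None] == np.arange(n_classes)[None, None, :]
    counts = oh.sum(axis=1)
    dsum = (oh * nb_d[:, :k, None]).sum(axis=1)
    tied = counts == counts.max(axis=1, keepdims=True)
    key = np.where(tied, dsum, np.inf)
    return np.argmin(key, axis=1)  # first minimum -> smallest class index


def _sorted_neighbors(model_X, model_y, Q, kmax):
    D = cdist(np.atleast_2d(Q), model_X)
    order = np.argsort(D, axis=1, kind="stable")[:, :kmax]  # stable: insertion order
    nb_y = model_y[order]
    nb_d = np.take_along_axis(D, order, axis=1)
    return nb_y, nb_d


def knn_predict(model: KnnModel, query: np.ndarray):
    """Predict one query or a batch; returns (labels, scores).

    Scores are the positive-class neighbor fractions (nan when the model
    has no positive class, e.g. three-class problems).
    """
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    if Q.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"query dimension {Q.shape[1]} != training dimension {model.X.shape[1]}"
        )
    nb_y, nb_d = _sorted_neighbors(model.X, model.y, Q, model.k)
    pred = _predict_from_sorted(nb_y, nb_d, model.k, len(model.classes))
    labels = np.array([model.classes[i] for i in pred])
    if model.positive in model.classes:
        pos = model.classes.index(model.positive)
        scores = (nb_y == pos).mean(axis=1)
    else:
        scores = np.full(Q.shape[0], np.nan)
    single = np.asarray(query).ndim == 1
    return (labels[0], float(scores[0])) if single else (labels, scores)


def cv_knn_accuracy(
    X: np.ndarray,
    labels: Sequence[str],
    seed: int,
    k_range: tuple[int, int] = (1, 25),
    n_folds: int = 5,
) -> tuple[float, int]:
    """Stratified n-fold CV accuracy, maximized over k in k_range.

    Returns (best accuracy, best k); accuracy ties prefer the smaller k.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels)))
    y = np.array([classes.index(l) for l in labels])
    kmin, kmax_req = k_range
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise SplitError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    kmax = min(kmax_req, min(len(tr) for tr, _ in splits))
    ks = list(range(kmin, kmax + 1))
    correct = {k: 0 for k in ks}
    total = 0
    for tr, va in splits:
        nb_y, nb_d = _sorted_neighbors(X[tr], y[tr], X[va], kmax)
        for k in ks:
            pred = _predict_from_sorted(nb_y, nb_d, k, len(classes))
            correct[k] += int(np.sum(pred == y[va]))
        total += len(va)
    accs = [correct[k] / total for k in ks]
    best = int(np.argmax(accs))  # first max -> smallest k
    return accs[best], ks[best]


def tune_k(
    X: np.ndarray,
    labels: Sequence[str],
    seed: int,
    k_range: tuple[int, int] = (1, 25),
) -> int:
    """k maximizing 5-fold stratified CV accuracy; ties -> smallest k."""
    _, k = cv_knn_accuracy(X, labels, seed, k_range)
    return k


def make_cv_evaluator(seed: int, k_range: tuple[int, int] = (1, 25)):
    """Accuracy callback for SFS: tuned k-NN CV accuracy on (X, y)."""

    def evaluator(X: np.ndarray, y: np.ndarray) -> float:
        return cv_knn_accuracy(X, y, seed, k_range)[0]

    return evaluator


def enumerate_channel_combos(
    n_channels: int, max_size: int = 4
) -> list[tuple[int, ...]]:
    """All channel-index subsets of sizes 1..max_size, lexicographic.

    For 20 channels and max_size 4 this yields 6195 combinations.
    """
    if not (1 <= max_size <= n_channels):
        raise ValueError(f"max_size {max_size} outside [1, {n_channels}]")
    out: list[tuple[int, ...]] = []
    for size in range(1, max_size + 1):
        out.extend(itertools.combinations(range(n_channels), size))
    return out


def _zscore_columns(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def combo_search(
    X_all: np.ndarray,
    labels: np.ndarray,
    instance_trial_ids: Sequence[str],
    split: SplitPlan,
    seed: int,
    combos: Optional[Sequence[tuple[int, ...]]] = None,
    k_range: tuple[int, int] = (1, 25),
    scale_features: bool = True,
    positive: Optional[str] = UNDERSTOOD,
) -> pd.DataFrame:
    """Evaluate every channel combination and rank by test accuracy.

    ``X_all`` is (n_instances, n_channels, n_features); ``labels`` and
    ``instance_trial_ids`` align with its first axis.  Per combination:
    z-score features by training statistics, tune k by CV on the
    training split, predict the test split, record accuracy and (for
    binary tasks) the confusion counts.  The returned frame is sorted by
    test CA descending (stable, so ties keep combination order); its top
    row is the reported result for the configuration.
    """
    X_all = np.asarray(X_all, dtype=float)
    labels = np.asarray(labels)
    tid = np.asarray(instance_trial_ids)
    tr_mask = np.isin(tid, list(split.train_ids))
    te_mask = np.isin(tid, list(split.test_ids))
    if combos is None:
        combos = enumerate_channel_combos(X_all.shape[1])
    binary = set(np.unique(labels)) == {UNDERSTOOD, NOT_UNDERSTOOD}
    rows = []
    for combo in combos:
        Xc = X_all[:, list(combo), :].reshape(X_all.shape[0], -1)
        Xtr, Xte = Xc[tr_mask], Xc[te_mask]
        if scale_features:
            Xtr, Xte = _zscore_columns(Xtr, Xte)
        ytr, yte = labels[tr_mask], labels[te_mask]
        k = tune_k(Xtr, ytr, seed, k_range)
        model = fit_knn(Xtr, ytr, k, positive=positive)
        pred, _ = knn_predict(model, Xte)
        row = {
            "combo": "+".join(str(c) for c in combo),
            "k": k,
            "ca": float(np.mean(pred == yte)),
        }
        if binary:
            row["tp"] = int(np.sum((yte == UNDERSTOOD) & (pred == UNDERSTOOD)))
            row["fn"] = int(np.sum((yte == UNDERSTOOD) & (pred == NOT_UNDERSTOOD)))
            row["tn"] = int(np.sum((yte == NOT_UNDERSTOOD) & (pred == NOT_UNDERSTOOD)))
            row["fp"] = int(np.sum((yte == NOT_UNDERSTOOD) & (pred == UNDERSTOOD)))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("ca", ascending=False, kind="stable").reset_index(drop=True)
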