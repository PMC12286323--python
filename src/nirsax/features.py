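"""Statistical features on numeric symbol sequences and SFS.

Five candidate statistics per (channel, window): mean, variance,
skewness, kurtosis, std — all population (1/n) moments, with skewness
m3 / var^{3/2} and kurtosis m4 / std^4 (non-excess: 3 for a Gaussian).
Degenerate (constant) sequences get skewness = kurtosis = 0.

Sequential forward selection greedily adds the statistic that most
improves a classifier-accuracy callback, stopping when nothing improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis", "std")

_EPS = 1e-12


@dataclass(frozen=True)
class FeatureMenu:
    available: tuple[str, ...] = FEATURE_NAMES
    selected: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        bad = set(self.selected) - set(self.available)
        if bad:
            raise ValueError(f"selected features not available: {sorted(bad)}")
        if not self.selected:
            raise ValueError("selection must be non-empty")

    @property
    def indices(self) -> list[int]:
        return [self.available.index(f) for f in self.selected]


@dataclass(frozen=True)
class FeatureVector:
    """Selected statistics for one instance over one channel combination."""

    trial_id: str
    channel_ids: tuple[int, ...]
    values: np.ndarray
    label: str


def moment_features(Z: np.ndarray, axis: int = -1) -> np.ndarray:
    """All five statistics along ``axis``, stacked on a new last axis.

    Output shape = Z.shape without ``axis`` + (5,), ordered as
    FEATURE_NAMES.
    """
    Z = np.asarray(Z, dtype=float)
    mu = Z.mean(axis=axis)
    d = Z - np.expand_dims(mu, axis)
    var = np.mean(d ** 2, axis=axis)
    std = np.sqrt(var)
    m3 = np.mean(d ** 3, axis=axis)
    m4 = np.mean(d ** 4, axis=axis)
    ok = var > _EPS
    skew = np.where(ok, m3 / np.where(ok, var, 1.0) ** 1.5, 0.0)
    kurt = np.where(ok, m4 / np.where(ok, var, 1.0) ** 2, 0.0)
    return np.stack([mu, var, skew, kurt, std], axis=-1)


def stat_features(z: Sequence[float], menu: FeatureMenu | None = None) -> np.ndarray:
    """The menu's selected statistics of one sequence, in menu order."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    menu = menu or FeatureMenu()
    all_vals = moment_features(z)
    lookup = dict(zip(FEATURE_NAMES, all_vals))
    return np.array([lookup[f] for f in menu.selected])


Evaluator = Callable[[np.ndarray, np.ndarray], float]


def sfs_select(
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Evaluator,
    available: tuple[str, ...] = FEATURE_NAMES,
) -> FeatureMenu:
    """Classical sequential forward selection over feature groups.

    ``X`` has shape (n_instances, n_channels, n_features); the feature
    axis is ordered as ``available`` and each candidate contributes its
    column for every channel.  Starting from the empty set, the feature
    whose addition maximizes ``evaluator`` accuracy is added; ties break
    toward the earlier menu entry; selection stops when no addition
    improves the score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 3 or X.shape[2] != len(available):
        raise ValueError(
            f"X must be (n, n_channels, {len(available)}), got {X.shape}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("sfs_select needs at least 2 classes")

    n = X.shape[0]
    chosen: list[int] = []
    best_score = -np.inf
    remaining = list(range(len(available)))
    while remaining:
        scores = []
        for f in remaining:
            cols = X[:, :, chosen + [f]].reshape(n, -1)
            scores.append(evaluator(cols, y))
        k = int(np.argmax(scores))  # first max -> menu-order tie-break
        if scores[k] <= best_score:
            break
        best_score = scores[k]
        chosen.append(remaining.pop(k))
    if not chosen:  # evaluator never improved on -inf: cannot happen, but guard
        chosen = [0]
    chosen_sorted = sorted(chosen)
    return FeatureMenu(available, tuple(available[i] for i in chosen_sorted))
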