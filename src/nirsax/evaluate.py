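"""Confusion-matrix metrics, ROC/AUC, and the polygon area metric (PAM).

PAM summarizes six metrics — CA, SE, SP, AUC, J (Jaccard), FM
(F-measure) — by placing them on the six spokes of a regular unit
hexagon in that cyclic order, joining the points into a polygon made of
six 60-degree triangles, and normalizing the polygon area by the full
hexagon area 6 * sqrt(3)/4 = 2.59807...:

    RA  = (sqrt(3)/4) * sum_i a_i * b_i       (a_i, b_i adjacent metrics)
    PAM = RA / 2.59807

PAM is 1 exactly when all six metrics are 1, lies in [0, 1], and is
non-decreasing in each metric.  The positive class is "understood".
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .labeling import NOT_UNDERSTOOD, UNDERSTOOD

logger = logging.getLogger(__name__)

HEXAGON_AREA = 6.0 * math.sqrt(3.0) / 4.0  # 2.598076...

# spoke order around the hexagon; PAM depends on it
PAM_ORDER = ("ca", "se", "sp", "auc", "j", "fm")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EvalReport:
    """The six PAM constituents plus precision and the PAM score."""

    ca: float
    se: float
    sp: float
    j: float
    fm: float
    precision: float
    auc: Optional[float] = None
    pam: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def confusion(
    true: Sequence[str], predicted: Sequence[str], positive: str = UNDERSTOOD
) -> ConfusionMatrix:
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted label lists differ in length")
    t_pos = true == positive
    p_pos = predicted == positive
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> EvalReport:
    """CA, SE, SP, J, FM, precision as plain confusion-matrix ratios."""
    return EvalReport(
        ca=_ratio(cm.tp + cm.tn, cm.total, "CA"),
        se=_ratio(cm.tp, cm.tp + cm.fn, "SE"),
        sp=_ratio(cm.tn, cm.tn + cm.fp, "SP"),
        j=_ratio(cm.tp, cm.tp + cm.fp + cm.fn, "J"),
        fm=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "FM"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str],
            positive: str = UNDERSTOOD) -> float:
    """Area under the empirical ROC (trapezoidal; tied scores count 1/2).

    Equivalent to the Mann-Whitney U statistic over positive/negative
    score pairs divided by n+ * n-.
    """
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pam(report: EvalReport) -> float:
    """Polygon area metric from the six constituents of ``report``.

    Metrics sit on the hexagon spokes in the order CA, SE, SP, AUC, J,
    FM (cyclic); RA sums the six adjacent-pair triangle areas.
    """
    if report.auc is None:
        raise ValueError("pam needs an AUC value")
    vals = [getattr(report, name) for name in PAM_ORDER]
    for name, v in zip(PAM_ORDER, vals):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    ra = (math.sqrt(3.0) / 4.0) * sum(
        vals[i] * vals[(i + 1) % 6] for i in range(6)
    )
    return ra / HEXAGON_AREA


def evaluate_binary(
    true: Sequence[str],
    predicted: Sequence[str],
    scores: Optional[Sequence[float]] = None,
    positive: str = UNDERSTOOD,
) -> EvalReport:
    """Full two-class report: ratios, AUC (if scores given), and PAM."""
    cm = confusion(true, predicted, positive)
    report = basic_metrics(cm)
    if scores is not None:
        report.auc = roc_auc(scores, true, positive)
        report.pam = pam(report)
    return report


def plot_pam(report: EvalReport, ax=None):
    """Radar-style hexagon plot of the six PAM constituents."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vals = [getattr(report, name) for name in PAM_ORDER]
    ang = np.linspace(0, 2 * np.pi, 7)[:6]
    ax.plot(np.r_[ang, ang[0]], np.r_[vals, vals[0]], "r-", lw=1.5)
    ax.fill(np.r_[ang, ang[0]], np.r_[vals, vals[0]], "r", alpha=0.25)
    ax.set_xticks(ang)
    ax.set_xticklabels([n.upper() for n in PAM_ORDER])
    ax.set_ylim(0, 1)
    if report.pam is not None:
        ax.set_title(f"PAM = {report.pam:.2%}")
    return ax
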