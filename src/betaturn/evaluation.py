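"""Assessment statistics for turn/non-turn and turn-type prediction.

All scalar measures derive from the per-residue confusion counts: true
positives p, true negatives n, false positives (over-predictions) o,
false negatives (under-predictions) u, and the total t = p + n + o + u.

    Q_total      = 100 (p + n) / t          overall accuracy (%)
    sensitivity  = 100 p / (p + u)          Q_obs (%)
    specificity  = 100 n / (n + o)          (%)
    MCC          = (pn - ou) / sqrt((p+o)(p+u)(n+o)(n+u))
    Q_pred       = 100 p / (p + o)          precision (%)
    S            = 100 (p + n - R) / (t - R)

where R = ((p+o)(p+u) + (n+o)(n+u)) / t is the expected number of
residues a marginal-preserving random prediction would get right; S is
the normalised percentage better than random (100 for a perfect
prediction, 0 at random-level agreement).

Metrics with a zero denominator are *undefined*, reported as None, and
never coerced to zero — "no positive predictions" must remain
distinguishable from "all positive predictions wrong".

ROC curves are built from real-valued decision scores (one point per
distinct threshold) and the area under the curve is computed with the
trapezium rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "mcc",
    "q_total",
    "sensitivity",
    "specificity",
    "q_pred",
    "s_score",
    "roc_curve",
    "auc",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-residue tallies: p (TP), n (TN), o (FP), u (FN)."""

    p: int
    n: int
    o: int
    u: int

    def __post_init__(self) -> None:
        if min(self.p, self.n, self.o, self.u) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def t(self) -> int:
        return self.p + self.n + self.o + self.u

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.p + other.p, self.n + other.n,
                               self.o + other.o, self.u + other.u)


@dataclass(frozen=True)
class MetricsReport:
    """All scalar scores for one channel; None marks an undefined metric."""

    q_total: float | None
    sensitivity: float | None
    specificity: float | None
    mcc: float | None
    q_pred: float | None
    s_score: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "q_total": self.q_total,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "q_pred": self.q_pred,
            "s_score": self.s_score,
            "auc": self.auc,
        }


def confusion(pred, truth) -> ConfusionCounts:
    """Count per-residue agreement between binary prediction and truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth have different lengths")
    return ConfusionCounts(
        p=int(np.sum((pred == 1) & (truth == 1))),
        n=int(np.sum((pred == 0) & (truth == 0))),
        o=int(np.sum((pred == 1) & (truth == 0))),
        u=int(np.sum((pred == 0) & (truth == 1))),
    )


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient in [-1, 1]; None if any marginal is zero."""
    denom = ((c.p + c.o) * (c.p + c.u) * (c.n + c.o) * (c.n + c.u))
    if denom == 0:
        return None
    return (c.p * c.n - c.o * c.u) / math.sqrt(float(denom))


def q_total(c: ConfusionCounts) -> float | None:
    """Percentage of correctly classified residues."""
    return 100.0 * (c.p + c.n) / c.t if c.t else None


def sensitivity(c: ConfusionCounts) -> float | None:
    """Percentage of observed positives predicted correctly (Q_obs)."""
    return 100.0 * c.p / (c.p + c.u) if (c.p + c.u) else None


def specificity(c: ConfusionCounts) -> float | None:
    """Percentage of observed negatives predicted correctly."""
    return 100.0 * c.n / (c.n + c.o) if (c.n + c.o) else None


def q_pred(c: ConfusionCounts) -> float | None:
    """Percentage of positive predictions that are correct (precision)."""
    return 100.0 * c.p / (c.p + c.o) if (c.p + c.o) else None


def s_score(c: ConfusionCounts) -> float | None:
    """Normalised percentage better than random.

    R = ((p+o)(p+u) + (n+o)(n+u)) / t is the expected number of correct
    residues under a random prediction with the same marginals;
    S = 100 (p + n - R) / (t - R).  Undefined (None) when t = R, i.e.
    when a marginal-preserving random predictor is already always right.
    """
    if c.t == 0:
        return None
    r = ((c.p + c.o) * (c.p + c.u) + (c.n + c.o) * (c.n + c.u)) / c.t
    if math.isclose(c.t, r):
        return None
    return 100.0 * (c.p + c.n - r) / (c.t - r)


def roc_curve(scores, truth) -> np.ndarray:
    """ROC points (FP rate, TP rate), one per distinct threshold.

    Points are ordered by increasing false-positive rate and include the
    (0, 0) and (1, 1) endpoints; tied scores share a point.  Requires
    both classes present in the truth.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.min() == truth.max():
        raise ValueError("ROC requires both classes present in the truth")
    fpr, tpr, _ = _sk_roc_curve(truth, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, (1.0, 1.0)])
    return pts


def auc(points) -> float:
    """Trapezium-rule area under ROC points sorted by FP rate."""
    pts = np.asarray(points, dtype=float)
    fpr, tpr = pts[:, 0], pts[:, 1]
    if np.any(np.diff(fpr) < 0):
        raise ValueError("ROC points must be sorted by false-positive rate")
    return float(np.trapezoid(tpr, fpr))


def metrics_report(c: ConfusionCounts,
                   roc_auc: float | None = None) -> MetricsReport:
    """Bundle every scalar measure for one channel's confusion counts."""
    return MetricsReport(
        q_total=q_total(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        mcc=mcc(c),
        q_pred=q_pred(c),
        s_score=s_score(c),
        auc=roc_auc,
    )
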