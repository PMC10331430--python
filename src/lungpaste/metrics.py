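"""Classification metrics: ROC/AUC, accuracy, F1.

AUC uses the rank (Mann-Whitney) formulation with ties contributing 1/2.
The decision rule everywhere is ``score >= threshold`` predicts abnormal,
with the abnormal class as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvalReport", "roc_auc", "roc_curve", "accuracy_f1", "confusion_counts"]


@dataclass
class EvalReport:
    auc: float
    accuracy: float
    f1: float
    threshold_used: float
    n_normal: int
    n_abnormal: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "threshold_used": self.threshold_used,
            "n_normal": self.n_normal,
            "n_abnormal": self.n_abnormal,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 (normal) or 1 (abnormal)")
    return s, y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; ties between classes contribute 1/2."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(fpr, tpr) points anchored at (0,0) and (1,1), thresholds descending."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    pts = [(0.0, 0.0)]
    for i in np.nonzero(distinct)[0]:
        pts.append((fps[i] / n_neg, tps[i] / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) at the rule ``score >= threshold`` => abnormal."""
    s, y = _validate(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, fn, tn


def accuracy_f1(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    """Accuracy and F1 (positive class = abnormal); all-negative F1 is 0."""
    tp, fp, fn, tn = confusion_counts(scores, labels, threshold)
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom > 0 else 0.0
    return accuracy, f1
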