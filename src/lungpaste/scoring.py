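"""KDE anomaly scores over feature embeddings.

The density of a query embedding z against the normal-training bank
{z_1..z_N} is A(z) = (1/N) sum_i exp(-||z - z_i||^2 / 2) (unit-bandwidth
Gaussian kernel, proportionality constant fixed to 1). The raw anomaly
score is -log A(z), computed stably via log-sum-exp so high-dimensional
densities that underflow still score correctly; higher = more anomalous.
Scores are min-max normalized to [0, 1] over the scored set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "ScoreSet",
    "ThresholdDecision",
    "ConstantScoreWarning",
    "kde_density",
    "kde_raw_scores",
    "normalize_scores",
    "select_threshold",
    "ensemble_scores",
]


class ConstantScoreWarning(UserWarning):
    """Emitted when a score set is constant and min-max normalization degenerates."""


@dataclass
class ScoreSet:
    """Raw and normalized anomaly scores for a set of images."""

    image_ids: np.ndarray
    raw_scores: np.ndarray
    normalized_scores: np.ndarray


@dataclass(frozen=True)
class ThresholdDecision:
    threshold: float
    f1_at_threshold: float
    selection_set_id: str = ""


def _as_bank(bank: np.ndarray) -> np.ndarray:
    b = np.asarray(bank, dtype=np.float64)
    if b.ndim != 2 or b.shape[0] == 0:
        raise ValueError("bank must be a non-empty (N, D) array")
    return b


def kde_density(z: np.ndarray, bank: np.ndarray, bandwidth: float = 1.0) -> float:
    """Gaussian-kernel density of one query against the bank."""
    b = _as_bank(bank)
    q = np.asarray(z, dtype=np.float64).ravel()
    if q.shape[0] != b.shape[1]:
        raise ValueError(f"dimension mismatch: query {q.shape[0]} vs bank {b.shape[1]}")
    d2 = np.sort(((b - q) ** 2).sum(axis=1))  # sorted sum: exactly permutation-invariant
    return float(np.mean(np.exp(-d2 / (2.0 * bandwidth**2))))


def kde_raw_scores(queries: np.ndarray, bank: np.ndarray, bandwidth: float = 1.0) -> np.ndarray:
    """Raw anomaly scores -log A(z) for a stack of queries (stable)."""
    b = _as_bank(bank)
    q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if q.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: queries {q.shape[1]} vs bank {b.shape[1]}")
    d2 = np.sort(cdist(q, b, metric="sqeuclidean"), axis=1)  # permutation-invariant sums
    log_density = logsumexp(-d2 / (2.0 * bandwidth**2), axis=1) - np.log(b.shape[0])
    return -log_density


def normalize_scores(raw_scores: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant input maps to all 0.5."""
    s = np.asarray(raw_scores, dtype=np.float64).ravel()
    if s.size == 0:
        raise ValueError("cannot normalize an empty score set")
    if s.size < 2:
        raise ValueError("normalization needs at least 2 scores")
    lo, hi = s.min(), s.max()
    if hi == lo:
        warnings.warn("constant scores: returning all 0.5", ConstantScoreWarning, stacklevel=2)
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def select_threshold(
    normalized_scores: np.ndarray, labels: np.ndarray, selection_set_id: str = ""
) -> ThresholdDecision:
    """F1-maximizing cut over all candidate thresholds.

    Decision rule: ``score >= threshold`` predicts abnormal (positive class).
    Candidates are the minimum score (all-positive) and the midpoints of
    consecutive sorted unique scores; ties break toward the lower threshold
    (higher sensitivity). The all-negative cut has F1 = 0 and never wins.
    """
    s = np.asarray(normalized_scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both classes present")
    uniq = np.unique(s)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_thr, best_f1 = float(candidates[0]), -1.0
    for thr in candidates:
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = _f1(tp, fp, fn)
        if f1 > best_f1:
            best_thr, best_f1 = float(thr), f1
    return ThresholdDecision(best_thr, best_f1, selection_set_id)


def ensemble_scores(
    score_sets: list[np.ndarray], image_ids: list[np.ndarray] | None = None
) -> np.ndarray:
    """Average >= 2 aligned normalized score sets, then re-normalize min-max."""
    if len(score_sets) < 2:
        raise ValueError("ensemble needs at least 2 score sets")
    arrays = [np.asarray(s, dtype=np.float64).ravel() for s in score_sets]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("score sets have mismatched lengths")
    if image_ids is not None:
        ids0 = np.asarray(image_ids[0])
        for ids in image_ids[1:]:
            if not np.array_equal(ids0, np.asarray(ids)):
                raise ValueError("image ids are misaligned across score sets")
    mean = np.mean(arrays, axis=0)
    return normalize_scores(mean)
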