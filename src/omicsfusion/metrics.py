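"""Scoring and rank-aggregation primitives.

ANOVA-F feature ranking, Matthews correlation coefficient (binary formula
and its multiclass confusion-matrix generalization), precision/recall,
Borda rank aggregation, the Canberra distance between ranked lists, and
studentized (bootstrap-t) confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "RankedList",
    "Interval",
    "anova_f_rank",
    "confusion_counts",
    "mcc",
    "binary_mcc",
    "mcc_score",
    "precision_recall",
    "borda_aggregate",
    "canberra_rank_distance",
    "studentized_bootstrap_ci",
]


@dataclass(frozen=True)
class RankedList:
    """Ordered feature ids (rank 1 first) with non-increasing scores."""

    feature_ids: tuple[str, ...]
    scores: tuple[float, ...]
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores differ in length")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")
        s = np.asarray(self.scores, dtype=float)
        if len(s) > 1 and np.any(np.diff(s) > 1e-12):
            raise ValueError("scores must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.feature_ids)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.feature_ids)

    def top(self, k: int) -> tuple[str, ...]:
        return self.feature_ids[:k]

    def positions(self) -> dict[str, int]:
        """1-based rank position of every feature."""
        return {f: i + 1 for i, f in enumerate(self.feature_ids)}


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("lower must not exceed upper")

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def _stable_rank(scores: np.ndarray, feature_ids: Sequence[str], tag: str) -> RankedList:
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        tuple(feature_ids[i] for i in order),
        tuple(float(scores[i]) for i in order),
        tag,
    )


def anova_f_rank(matrix: np.ndarray, labels, feature_ids: Sequence[str] | None = None) -> RankedList:
    """Rank features by one-way ANOVA F statistic (descending).

    Constant features get F = 0 and sink to the bottom; a feature with zero
    within-class variance but distinct class means gets F = +inf and ranks
    first. Ties keep the input (layer order, feature index) order.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels.codes() if hasattr(labels, "codes") else labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ANOVA ranking needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError(
            f"every class needs >=2 samples for ANOVA; class {classes[np.argmin(counts)]} "
            f"has {counts.min()}"
        )
    if feature_ids is None:
        feature_ids = [f"f{j + 1}" for j in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    return _stable_rank(F, list(feature_ids), "anova_f")


def confusion_counts(y_true, y_pred, positive=1) -> tuple[int, int, int, int]:
    """Binary (TP, TN, FP, FN) counts with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, tn, fp, fn


def binary_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Any zero factor in the denominator yields 0 by convention.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("at least one scored sample required")
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return float(num / np.sqrt(den))


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation from a k x k confusion matrix (rows = truth).

    Uses the multi-category generalization (correlation of the confusion
    matrix); for k = 2 it coincides with the binary formula. A zero factor
    in the denominator yields 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    s = C.sum()
    if s == 0:
        raise ValueError("at least one scored sample required")
    t = C.sum(axis=1)  # true counts per class
    p = C.sum(axis=0)  # predicted counts per class
    c = np.trace(C)
    num = c * s - float(t @ p)
    den = np.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def mcc_score(y_true, y_pred) -> float:
    """MCC of label vectors (any hashable labels, binary or multiclass)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return mcc(_sk_confusion(y_true, y_pred, labels=labels))


def precision_recall(confusion: np.ndarray, positive: int = 1) -> tuple[float, float]:
    """Precision and recall from a confusion matrix (rows = truth).

    Binary: TP/(TP+FP) and TP/(TP+FN) for the positive class (index into
    the matrix). Multiclass (k > 2): macro averages over classes. The 0/0
    cases map to 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    k = C.shape[0]
    if k == 2:
        if positive not in (0, 1):
            raise ValueError(f"unknown positive class index {positive}")
        idx = [positive]
    else:
        idx = list(range(k))
    precs, recs = [], []
    for i in idx:
        tp = C[i, i]
        pred = C[:, i].sum()
        true = C[i, :].sum()
        precs.append(tp / pred if pred > 0 else 0.0)
        recs.append(tp / true if true > 0 else 0.0)
    return float(np.mean(precs)), float(np.mean(recs))


def borda_aggregate(lists: Sequence[RankedList], allow_partial: bool = False) -> RankedList:
    """Borda aggregation of ranked lists over one feature universe.

    Each feature scores sum over lists of (L - position), L the universe
    size and positions 1-based. Output sorted by descending score; exact
    ties broken by feature id. A single list is returned unchanged.

    With ``allow_partial`` the lists may cover different subsets of one
    universe (e.g. split-local restrictions): L becomes the union size and
    a list contributes nothing for features it does not rank. The default
    is strict: mismatched universes are an error.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    if len(lists) == 1:
        return lists[0]
    universe = set(lists[0].universe)
    for rl in lists[1:]:
        if rl.universe != lists[0].universe:
            if not allow_partial:
                diff = sorted(universe ^ set(rl.universe))
                raise ValueError(f"feature universes differ; symmetric difference: {diff}")
            universe |= set(rl.universe)
    L = len(universe)
    score: dict[str, int] = {f: 0 for f in sorted(universe)}
    for rl in lists:
        for pos, f in enumerate(rl.feature_ids, start=1):
            score[f] += L - pos
    ordered = sorted(score, key=lambda f: (-score[f], f))
    return RankedList(tuple(ordered), tuple(float(score[f]) for f in ordered), "borda")


def canberra_rank_distance(r1: RankedList, r2: RankedList) -> float:
    """Canberra distance between two full rankings of one universe.

    Sum over features of |p1 - p2| / (p1 + p2) with 1-based positions;
    0 iff the orderings are identical.
    """
    if r1.universe != r2.universe:
        diff = sorted(r1.universe ^ r2.universe)
        raise ValueError(f"feature universes differ; symmetric difference: {diff}")
    pos1 = r1.positions()
    pos2 = r2.positions()
    return float(sum(abs(pos1[f] - pos2[f]) / (pos1[f] + pos2[f]) for f in pos1))


def studentized_bootstrap_ci(values, level: float = 0.95, B: int = 1000,
                             inner: int = 100, seed: int = 0) -> Interval:
    """Studentized (bootstrap-t) confidence interval for the mean.

    Resamples B times; each resample's statistic is studentized with a
    nested-bootstrap standard error (``inner`` resamples); the interval is
    read off the t* quantiles against the plug-in standard error.
    Deterministic given the seed; an all-equal input yields a zero-width
    interval.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    if B < 100:
        raise ValueError("B must be >= 100")
    theta = float(x.mean())
    if np.ptp(x) == 0:
        return Interval(theta, theta, level)
    rng = np.random.default_rng(int(seed))
    idx = rng.integers(0, n, size=(B, n))
    samples = x[idx]
    theta_star = samples.mean(axis=1)
    inner_idx = rng.integers(0, n, size=(B, inner, n))
    inner_samples = samples[np.arange(B)[:, None, None], inner_idx]
    se_star = inner_samples.mean(axis=2).std(axis=1, ddof=1)
    ok = se_star > 0
    if not ok.any():
        return Interval(theta, theta, level)
    t = (theta_star[ok] - theta) / se_star[ok]
    se_hat = float(x.std(ddof=1) / np.sqrt(n))
    alpha = 1.0 - level
    t_hi = float(np.quantile(t, 1.0 - alpha / 2.0))
    t_lo = float(np.quantile(t, alpha / 2.0))
    lo, hi = theta - t_hi * se_hat, theta - t_lo * se_hat
    return Interval(min(lo, hi), max(lo, hi), level)
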