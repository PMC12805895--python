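"""Evaluation protocol and wet-lab validation arithmetic.

Covers the stratified 70/15/15 three-way partition, stratified k-fold
cross-validation, the standard binary-classification metrics and their
curves (ROC, precision-recall; AUCs by the trapezoidal rule), and the qPCR
bookkeeping used to validate candidates: ΔCt relative expression
``2^-(Ct_target - Ct_reference)``, fold enrichment between conditions, and
the Ct-threshold expression call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataPartition:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    raw = [total * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = total - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_split(
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DataPartition:
    """Stratified three-way split with per-class largest-remainder rounding.

    Every class is shuffled independently (seeded) and allocated to the
    train/test/validation sets so that per-class counts deviate from the
    target fractions by at most one instance.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 3:
            raise ValueError(
                f"class {cls} has {len(idx)} instances; need at least one per set"
            )
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        # very small classes: guarantee every partition sees the class, at
        # the cost of exceeding the +-1 stratification bound for it
        while min(counts) == 0:
            counts[counts.index(max(counts))] -= 1
            counts[counts.index(0)] += 1
        bounds = np.cumsum(counts)
        parts[0].append(idx[: bounds[0]])
        parts[1].append(idx[bounds[0] : bounds[1]])
        parts[2].append(idx[bounds[1] :])
    return DataPartition(
        train=np.sort(np.concatenate(parts[0])),
        test=np.sort(np.concatenate(parts[1])),
        validation=np.sort(np.concatenate(parts[2])),
    )


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint folds covering all rows; per-fold class counts within ±1
    of the even allocation."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer instances ({len(idx)}) than k={k}")
        rng.shuffle(idx)
        for f in range(k):
            folds[f].append(idx[f::k])
    return [np.sort(np.concatenate(f)) for f in folds]


# ---------------------------------------------------------------------------
# confusion-count metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_calls(cls, calls: Sequence[int], labels: Sequence[int]) -> "ConfusionCounts":
        c = np.asarray(calls)
        y = np.asarray(labels)
        return cls(
            tp=int(np.sum((c == 1) & (y == 1))),
            tn=int(np.sum((c == 0) & (y == 0))),
            fp=int(np.sum((c == 1) & (y == 0))),
            fn=int(np.sum((c == 0) & (y == 1))),
        )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    if denom == 0:
        logger.warning("no predicted positives; precision defined as 0")
        return 0.0
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    if denom == 0:
        logger.warning("no actual positives; recall defined as 0")
        return 0.0
    return c.tp / denom


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def confusion_normalized(c: ConfusionCounts) -> np.ndarray:
    """Row-normalised 2x2 matrix; rows ordered (positive, negative) as
    (TP-rate, FN-rate) / (FP-rate, TN-rate). An empty true class yields a
    zero row with a warning."""
    pos = c.tp + c.fn
    neg = c.fp + c.tn
    out = np.zeros((2, 2))
    if pos:
        out[0] = [c.tp / pos, c.fn / pos]
    else:
        logger.warning("no positive instances; normalised row is zero")
    if neg:
        out[1] = [c.fp / neg, c.tn / neg]
    else:
        logger.warning("no negative instances; normalised row is zero")
    return out


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """(FPR, TPR) points over all distinct-score thresholds."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def pr_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """(recall, precision) points over all distinct-score thresholds, in
    ascending-recall threshold order (adjacency preserved so the trapezoid
    integrates the step curve correctly through tied recalls)."""
    prec, rec, _ = precision_recall_curve(
        np.asarray(labels), np.asarray(scores, dtype=float)
    )
    return np.column_stack([rec[::-1], prec[::-1]])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under a curve given as threshold-ordered (x, y)
    points with non-decreasing x."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    return auc(roc_points(scores, labels))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    return auc(pr_points(scores, labels))


# ---------------------------------------------------------------------------
# reports and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    pr_auc: float
    confusion: ConfusionCounts
    confusion_normalized: np.ndarray
    roc: np.ndarray = field(repr=False, default=None)
    pr: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "confusion": {
                "tp": self.confusion.tp, "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn,
            },
        }


def evaluate(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> EvalReport:
    """Full report: thresholded confusion metrics plus ROC/PR curves."""
    from .model import classify

    calls = classify(np.asarray(scores), threshold)
    c = ConfusionCounts.from_calls(calls, labels)
    roc = roc_points(scores, labels)
    pr = pr_points(scores, labels)
    return EvalReport(
        accuracy=accuracy(c),
        precision=precision(c),
        recall=recall(c),
        f1=f1(c),
        roc_auc=auc(roc),
        pr_auc=auc(pr),
        confusion=c,
        confusion_normalized=confusion_normalized(c),
        roc=roc,
        pr=pr,
    )


def cross_validate(data, hp=None, k: int = 5, seed: int = 0,
                   threshold: float = 0.5) -> dict:
    """Stratified k-fold CV: per-fold reports plus mean ± sd of the scalar
    metrics, and the pooled out-of-fold scores/labels."""
    from .model import LabeledDataset, predict_proba, train

    assert isinstance(data, LabeledDataset)
    folds = stratified_kfold(data.labels, k=k, seed=seed)
    reports: list[EvalReport] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for held in folds:
        mask = np.ones(len(data), dtype=bool)
        mask[held] = False
        bundle = train(data.subset(np.flatnonzero(mask)), hp)
        scores = predict_proba(bundle, data.features.iloc[held])
        reports.append(evaluate(scores, data.labels[held], threshold))
        pooled_scores.append(scores)
        pooled_labels.append(data.labels[held])
    metrics = ("accuracy", "precision", "recall", "f1", "roc_auc", "pr_auc")
    summary = {
        m: {
            "mean": float(np.mean([getattr(r, m) for r in reports])),
            "sd": float(np.std([getattr(r, m) for r in reports])),
        }
        for m in metrics
    }
    return {
        "folds": reports,
        "summary": summary,
        "pooled_scores": np.concatenate(pooled_scores),
        "pooled_labels": np.concatenate(pooled_labels),
    }


# ---------------------------------------------------------------------------
# qPCR arithmetic
# ---------------------------------------------------------------------------

def relative_expression(ct_target: float, ct_reference: float) -> float:
    """ΔCt relative expression: ``2^-(Ct_target - Ct_reference)``."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


def fold_enrichment(expr_a: float, expr_b: float) -> float:
    """Ratio of two relative-expression values (condition A over B)."""
    if expr_b == 0:
        raise ValueError("reference expression must be nonzero")
    return expr_a / expr_b


def expression_call(ct: float, threshold_ct: float = 37.9) -> str:
    """"expressed" iff amplification occurs strictly before the negative-
    control threshold cycle (Ct < threshold), else "not_detected"."""
    return "expressed" if ct < threshold_ct else "not_detected"
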