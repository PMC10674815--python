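"""Classification and calibration metrics.

Accuracy, sensitivity and specificity are exact ratios of confusion-matrix
cells with 'good' as the positive class. AUROC uses the rank-based
Mann-Whitney formulation — the probability that a random positive outranks a
random negative, with ties credited 1/2 — which equals trapezoidal
integration of the empirical ROC curve. The Brier score is the mean squared
difference between the probability assigned to 'good' and the 0/1 indicator
of 'good' (for two classes this single-class form is equivalent, up to the
conventional factor, to the two-class sum, and keeps the 0-1 range). The
most-confident statistic is the per-instance maximum class probability,
bounded below by 0.5 for two classes.

Metrics with an empty denominator (e.g. specificity with no negatives) are
undefined and returned as NaN — an explicit marker, never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

POSITIVE = "good"
NEGATIVE = "bad"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with 'good' as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("at least one evaluated instance is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ProbPredictions:
    """Per-instance class probabilities (columns bad, good) plus actuals."""

    probs: np.ndarray
    actuals: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.actuals = np.asarray(self.actuals)
        if self.probs.ndim != 2 or self.probs.shape[1] != 2:
            raise ValueError("probs must be n x 2 (bad, good)")
        if self.probs.shape[0] < 1:
            raise ValueError("at least one prediction is required")
        if len(self.actuals) != self.probs.shape[0]:
            raise ValueError("actuals length must match probs")
        if np.any(self.probs < -1e-9) or np.any(self.probs > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability pair must sum to 1")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def p_good(self) -> np.ndarray:
        return self.probs[:, 1]


@dataclass
class MetricsReport:
    """All evaluation metrics for one model on one test matrix."""

    accuracy: float
    sensitivity: float
    specificity: float
    auroc: float
    brier: float
    confidence_profile: np.ndarray
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        def clean(v: float):
            return None if (isinstance(v, float) and math.isnan(v)) else float(v)

        return {
            "accuracy": clean(self.accuracy),
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "auroc": clean(self.auroc),
            "brier": clean(self.brier),
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
        }


# ---------------------------------------------------------------------------


def confusion(actual, predicted, positive: str = POSITIVE) -> ConfusionCounts:
    """Tally confusion cells; the positive class defaults to 'good'."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.shape} actual vs {predicted.shape} predicted"
        )
    pos_a = actual == positive
    pos_p = predicted == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_a & pos_p)),
        fp=int(np.sum(~pos_a & pos_p)),
        tn=int(np.sum(~pos_a & ~pos_p)),
        fn=int(np.sum(pos_a & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when there are no positives."""
    denom = c.tp + c.fn
    return math.nan if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when there are no negatives."""
    denom = c.tn + c.fp
    return math.nan if denom == 0 else c.tn / denom


def brier(p: ProbPredictions) -> float:
    """Mean squared difference between P(good) and the 'good' indicator."""
    outcome = (p.actuals == POSITIVE).astype(np.float64)
    return float(np.mean((p.p_good - outcome) ** 2))


def auroc(scores, actuals, positive: str = POSITIVE) -> float:
    """Rank-based (Mann-Whitney) AUROC with ties credited 1/2.

    NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    actuals = np.asarray(actuals)
    pos = actuals == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)  # average ranks handle ties -> 1/2 credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def most_confident(p: ProbPredictions) -> np.ndarray:
    """Per-instance maximum class probability; in [0.5, 1] for two classes."""
    return p.probs.max(axis=1)


def evaluate(model, test) -> MetricsReport:
    """Run one prediction pass and compute every metric from it.

    AUROC is scored on the 'good'-class probability; predicted labels follow
    the model's tie-to-'bad' rule.
    """
    preds = model.predict_proba(test)
    labels = np.where(preds.p_good > preds.probs[:, 0], POSITIVE, NEGATIVE)
    counts = confusion(preds.actuals, labels)
    return MetricsReport(
        accuracy=accuracy(counts),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        auroc=auroc(preds.p_good, preds.actuals),
        brier=brier(preds),
        confidence_profile=most_confident(preds),
        counts=counts,
    )
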