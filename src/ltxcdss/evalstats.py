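"""Diagnostic-accuracy mathematics: confusion matrix, accuracy/sensitivity/
specificity, and exact (Clopper-Pearson) binomial confidence intervals.

All metrics are binomial proportions, so each carries the same exact
interval machinery: the 100(1-a)% Clopper-Pearson interval for x successes
in n trials is

    lower = BetaInv(a/2;     x,     n - x + 1)      (0 when x = 0)
    upper = BetaInv(1 - a/2; x + 1, n - x)          (1 when x = n)

with the closed forms (a/2)^(1/n) for the lower bound at x = n and
1 - (a/2)^(1/n) for the upper bound at x = 0.  Exact intervals are
conservative: empirical coverage is at least nominal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import beta as _beta

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "confusion_from_labels",
    "clopper_pearson",
    "accuracy",
    "sensitivity",
    "specificity",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts; positive = eligible transplant candidate."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    successes: int
    n: int
    level: float = 0.95
    method: str = "clopper-pearson"

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError("interval must satisfy 0 <= low <= point <= high <= 1")

    @property
    def percent(self) -> float:
        return 100.0 * self.point

    def format_percent(self) -> str:
        """Render like the clinical reporting style: '84.75% (73.01-92.78%; 95% CI)'."""
        return (
            f"{self.percent:.2f}% ({100 * self.ci_low:.2f}-{100 * self.ci_high:.2f}%; "
            f"{self.level:.0%} CI)"
        )


def confusion_from_labels(predicted: Sequence[bool], actual: Sequence[bool]) -> ConfusionMatrix:
    """Tally prediction/reference pairs into a confusion matrix.

    ``predicted`` is the system's eligibility call, ``actual`` the physician
    reference; TP counts pairs where both say eligible.
    """
    if len(predicted) != len(actual):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels")
    if not predicted:
        raise ValueError("need at least one prediction/label pair")
    tp = fn = fp = tn = 0
    for p, a in zip(predicted, actual):
        if a:
            if p:
                tp += 1
            else:
                fn += 1
        else:
            if p:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval from beta quantiles."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(_beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(_beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def _proportion(successes: int, denominator: int, metric: str, level: float) -> MetricEstimate:
    if denominator <= 0:
        raise UndefinedMetricError(f"{metric} is undefined: its denominator is zero")
    low, high = clopper_pearson(successes, denominator, level)
    return MetricEstimate(
        point=successes / denominator, ci_low=low, ci_high=high,
        successes=successes, n=denominator, level=level,
    )


def accuracy(cm: ConfusionMatrix, level: float = 0.95) -> MetricEstimate:
    """(TP + TN) / (TP + TN + FP + FN) with exact CI."""
    return _proportion(cm.tp + cm.tn, cm.total, "accuracy", level)


def sensitivity(cm: ConfusionMatrix, level: float = 0.95) -> MetricEstimate:
    """TP / (TP + FN) with exact CI; undefined without actual positives."""
    return _proportion(cm.tp, cm.positives, "sensitivity", level)


def specificity(cm: ConfusionMatrix, level: float = 0.95) -> MetricEstimate:
    """TN / (TN + FP) with exact CI; undefined without actual negatives."""
    return _proportion(cm.tn, cm.negatives, "specificity", level)
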