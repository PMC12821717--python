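"""Slide-level evaluation statistics.

Confusion counts from paired binary calls, the derived sensitivity /
specificity / accuracy rates, the Youden index J = sensitivity +
specificity - 1, ROC curves over a melanocyte-density cutoff grid
(default 15..45 in steps of 5, predicted positive when the slide's
maximum density >= cutoff), trapezoidal AUC with (0,0)/(1,1) anchoring,
and Youden-optimal cutoff selection. Also the +-5-count concordance rule
for comparing two manual-style counts, and exact half-up percentage
formatting for composition tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    InputError,
    InsufficientPointsError,
    UndefinedRateError,
)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCPoint:
    cutoff: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0 <= self.tpr <= 1 and 0 <= self.fpr <= 1):
            raise DomainError("rates must lie in [0, 1]")

    @property
    def youden(self) -> float:
        return self.tpr - self.fpr


@dataclass
class ROCConfig:
    cutoff_grid: tuple = (15, 20, 25, 30, 35, 40, 45)
    anchor_endpoints: bool = True

    def __post_init__(self) -> None:
        grid = tuple(self.cutoff_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("cutoff_grid must be non-empty and strictly increasing")
        self.cutoff_grid = grid


@dataclass
class AgreementConfig:
    count_tolerance: int = 5

    def __post_init__(self) -> None:
        if self.count_tolerance < 0:
            raise ConfigurationError("count_tolerance must be >= 0")


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): proportion of truly positive slides identified."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("no positive slides: sensitivity undefined")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): proportion of truly negative slides identified."""
    if c.tn + c.fp == 0:
        raise UndefinedRateError("no negative slides: specificity undefined")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total: proportion of correct calls."""
    if c.total == 0:
        raise UndefinedRateError("empty confusion matrix: accuracy undefined")
    return (c.tp + c.tn) / c.total


def youden(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1, in [-1, 1]."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise DomainError("sensitivity and specificity must lie in [0, 1]")
    return sens + spec - 1.0


def compare_calls(pred, truth) -> ConfusionCounts:
    """Tally a confusion matrix from paired binary call lists."""
    pred = [bool(p) for p in pred]
    truth = [bool(t) for t in truth]
    if len(pred) != len(truth):
        raise InputError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    c = ConfusionCounts()
    for p, t in zip(pred, truth):
        if p and t:
            c.tp += 1
        elif p and not t:
            c.fp += 1
        elif not p and t:
            c.fn += 1
        else:
            c.tn += 1
    return c


def count_agreement(a: int, b: int, config: AgreementConfig | None = None) -> bool:
    """Two counts are concordant when they differ by less than the tolerance
    (a deviation of >= 5 melanocytes counts as inconsistent by default)."""
    config = config or AgreementConfig()
    if a < 0 or b < 0:
        raise DomainError("counts must be non-negative")
    return abs(a - b) < config.count_tolerance


def proportion(k: int, n: int) -> float:
    """Percentage 100*k/n rounded half-up to two decimals."""
    if n <= 0:
        raise DomainError("n must be positive")
    if k < 0 or k > n:
        raise DomainError("need 0 <= k <= n")
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(max_densities, truth, config: ROCConfig | None = None) -> list[ROCPoint]:
    """One ROC point per grid cutoff; a slide is called positive when its
    maximum window density >= cutoff. Points are sorted by (fpr, tpr);
    (0,0) and (1,1) anchors are appended when enabled."""
    config = config or ROCConfig()
    dens = np.asarray(list(max_densities), dtype=float)
    tr = np.asarray([bool(t) for t in truth])
    if len(dens) != len(tr):
        raise InputError("densities and truth must have equal length")
    if tr.all() or (~tr).all():
        raise UndefinedRateError("single-class truth: ROC rates undefined")
    points = []
    for cut in config.cutoff_grid:
        c = compare_calls(dens >= cut, tr)
        points.append(ROCPoint(cutoff=float(cut), tpr=sensitivity(c), fpr=1 - specificity(c)))
    points.sort(key=lambda p: (p.fpr, p.tpr))
    if config.anchor_endpoints:
        if not any(p.fpr == 0 and p.tpr == 0 for p in points):
            points.insert(0, ROCPoint(cutoff=float("inf"), tpr=0.0, fpr=0.0))
        if not any(p.fpr == 1 and p.tpr == 1 for p in points):
            points.append(ROCPoint(cutoff=float("-inf"), tpr=1.0, fpr=1.0))
    return points


def auc(points: list[ROCPoint]) -> float:
    """Trapezoidal area under the fpr-sorted ROC polyline."""
    if len(points) < 2:
        raise InsufficientPointsError("need at least 2 ROC points")
    pts = sorted(points, key=lambda p: (p.fpr, p.tpr))
    fpr = np.array([p.fpr for p in pts])
    tpr = np.array([p.tpr for p in pts])
    return float(np.trapezoid(tpr, fpr))


def select_cutoff(points: list[ROCPoint]) -> float:
    """Grid cutoff maximising the Youden index; ties go to the larger cutoff.

    Anchor points (infinite pseudo-cutoffs) never win a tie against a real
    grid cutoff."""
    if not points:
        raise InsufficientPointsError("no ROC points")
    finite = [p for p in points if np.isfinite(p.cutoff)] or list(points)
    best = max(finite, key=lambda p: (p.youden, p.cutoff))
    return best.cutoff


def summarize(c: ConfusionCounts) -> dict:
    """All derived rates of a confusion matrix as a JSON-ready dict."""
    sens = sensitivity(c)
    spec = specificity(c)
    return {
        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": accuracy(c),
        "youden": youden(sens, spec),
    }
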