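"""ROC analysis and Youden-optimal threshold selection.

The positive class may sit at the low or the high end of the score scale
(``positive_class_low`` / ``positive_class_high``); when unspecified, the
orientation giving AUC >= 0.5 is chosen.  AUC is the Mann-Whitney
probability P(score_pos beats score_neg) with half credit for ties, which
equals the trapezoidal area under the empirical curve.  Reported optimal
thresholds are placed at the midpoint between adjacent distinct scores, so
the published open-interval rules (e.g. "score < t detects the positive
class") are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

POSITIVE_LOW = "positive_class_low"
POSITIVE_HIGH = "positive_class_high"


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # distinct observed scores plus sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    J: float
    sensitivity: float
    specificity: float
    direction: str


def _apply(scores: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    """Predicted-positive mask for the open-interval rule."""
    if direction == POSITIVE_LOW:
        return scores < threshold
    return scores > threshold


def _positive_fraction(
    scores: np.ndarray, thresholds: np.ndarray, direction: str
) -> np.ndarray:
    """Fraction of ``scores`` predicted positive at each threshold
    (vectorized equivalent of :func:`_apply` + mean)."""
    s = np.sort(scores)
    if direction == POSITIVE_LOW:
        return np.searchsorted(s, thresholds, side="left") / len(s)
    return (len(s) - np.searchsorted(s, thresholds, side="right")) / len(s)


def roc_curve(scores, labels, direction: str | None = None) -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels`` (1 = positive).

    ``thresholds`` are the distinct observed scores framed by sentinels
    just outside the observed range; ``sensitivity``/``specificity`` are the
    operating points of the rule ``score < t`` (positive-low) or
    ``score > t`` (positive-high) at each threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(s)
    auc_high = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if direction is None:
        direction = POSITIVE_HIGH if auc_high >= 0.5 else POSITIVE_LOW
    elif direction not in (POSITIVE_LOW, POSITIVE_HIGH):
        raise ValueError(f"unknown direction {direction!r}")
    auc = auc_high if direction == POSITIVE_HIGH else 1.0 - auc_high

    distinct = np.unique(s)
    span = distinct[-1] - distinct[0] if len(distinct) > 1 else 1.0
    thresholds = np.concatenate(
        [[distinct[0] - 0.5 * span], distinct, [distinct[-1] + 0.5 * span]]
    )
    sens = _positive_fraction(s[y], thresholds, direction)
    spec = 1.0 - _positive_fraction(s[~y], thresholds, direction)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        direction=direction,
        scores=s,
        labels=y,
    )


def auc(roc: RocResult) -> float:
    """Area under the curve (Mann-Whitney with half credit for ties)."""
    return roc.auc


def candidate_cuts(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus outside sentinels."""
    d = np.unique(np.asarray(scores, dtype=float))
    if len(d) == 1:
        return np.array([d[0] - 0.5, d[0] + 0.5])
    mids = (d[:-1] + d[1:]) / 2.0
    lo = d[0] - (d[1] - d[0]) / 2.0
    hi = d[-1] + (d[-1] - d[-2]) / 2.0
    return np.concatenate([[lo], mids, [hi]])


def youden_optimal_threshold(roc: RocResult) -> ThresholdChoice:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward higher specificity, then toward the cut
    closest to the grand score median, then toward the lower threshold.
    """
    cuts = candidate_cuts(roc.scores)
    pos = roc.scores[roc.labels]
    neg = roc.scores[~roc.labels]
    sens = _positive_fraction(pos, cuts, roc.direction)
    spec = 1.0 - _positive_fraction(neg, cuts, roc.direction)
    j = sens + spec - 1.0
    med = float(np.median(roc.scores))
    order = sorted(
        range(len(cuts)),
        key=lambda i: (-j[i], -spec[i], abs(cuts[i] - med), cuts[i]),
    )
    best = order[0]
    return ThresholdChoice(
        threshold=float(cuts[best]),
        J=float(j[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        direction=roc.direction,
    )


def auc_gaussian_closed_form(
    mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
) -> float:
    """AUC of two Gaussian score distributions:
    Phi(|mean_pos - mean_neg| / sqrt(sd_pos^2 + sd_neg^2))."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    delta = abs(mean_pos - mean_neg)
    return float(sps.norm.cdf(delta / np.hypot(sd_pos, sd_neg)))
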