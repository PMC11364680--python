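"""ROC construction, AUC and Youden-index threshold selection on AI scores.

The test-positivity convention throughout is ``score >= threshold`` is
positive. Candidate thresholds are the distinct observed scores plus a
sentinel above the maximum, so the maximization of Youden's J
(sensitivity + specificity - 1) is exact — no discretization grid. Ties in
J are broken toward the lowest qualifying threshold, which favors
sensitivity, the natural preference in a screening setting.

The area under the ROC curve is computed by the trapezoid rule over the
operating points, which on this threshold set equals the Mann-Whitney
concordance probability with ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocCurve:
    """Operating characteristics at every distinct observed score.

    ``thresholds`` is ascending and ends with a sentinel above the maximum
    score (sensitivity 0, specificity 1); at the lowest observed score
    sensitivity is 1. ``tp``/``tn`` hold exact integer counts so downstream
    maximizations are free of floating-point ties.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ThresholdResult:
    """The selected operating point of a ROC curve."""

    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    tie_break: str = "lowest"


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if y.dtype != bool:
        y = y.astype(bool)
    if s.shape != y.shape:
        raise ValidationError(f"scores and labels differ in length: {s.size} vs {y.size}")
    if s.size == 0:
        raise DegenerateInputError("empty input")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if y.all() or (~y).all():
        raise DegenerateInputError("both classes must be present")
    return s, y


def build_roc(scores, labels) -> RocCurve:
    """Build the ROC curve of *scores* against boolean *labels*.

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold; each operating point counts ``score >= threshold`` as
    test-positive.
    """
    s, y = _check_scores_labels(scores, labels)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    thr = np.unique(s)
    thr = np.append(thr, thr[-1] + 1.0)  # sentinel: nothing is positive
    tp = pos.size - np.searchsorted(pos, thr, side="left")
    tn = np.searchsorted(neg, thr, side="left")
    return RocCurve(
        thresholds=thr,
        sensitivity=tp / pos.size,
        specificity=tn / neg.size,
        tp=tp,
        tn=tn,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def auc(curve: RocCurve) -> float:
    """Area under *curve* by the trapezoid rule.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    # thresholds ascend, so (fpr, tpr) descend from (1, 1) to (0, 0)
    return float(np.trapezoid(tpr[::-1], fpr[::-1]))


def _auc_rank(s: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (fast path for bootstrapping)."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_threshold(curve: RocCurve, tie_break: str = "lowest") -> ThresholdResult:
    """Select the threshold maximizing Youden's J = sens + spec - 1.

    The maximization is exact on integer counts; ties go to the lowest
    (default) or highest qualifying threshold.
    """
    if tie_break not in ("lowest", "highest"):
        raise ConfigurationError(f"unknown tie_break {tie_break!r}")
    # tp*n_neg + tn*n_pos is n_pos*n_neg*(sens+spec): same argmax, exact ints
    objective = curve.tp * curve.n_neg + curve.tn * curve.n_pos
    best = objective.max()
    idx_all = np.flatnonzero(objective == best)
    idx = int(idx_all[0] if tie_break == "lowest" else idx_all[-1])
    sens = float(curve.sensitivity[idx])
    spec = float(curve.specificity[idx])
    return ThresholdResult(
        threshold=float(curve.thresholds[idx]),
        youden_j=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        tie_break=tie_break,
    )


def auc_bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                     seed=None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUC.

    Visits are resampled with replacement; a replicate that draws a single
    class is redrawn (and logged). Reproducible given *seed*.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ConfigurationError("level must be in (0, 1)")
    s, y = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    n = s.size
    vals = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.any() and not yy.all():
                break
            redraws += 1
            if redraws > 1000 * n_boot:
                raise DegenerateInputError("bootstrap cannot find two-class resamples")
        vals[i] = _auc_rank(s[idx], yy)
    if redraws:
        logger.warning("redrew %d single-class bootstrap replicates", redraws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


class YoudenThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier whose decision threshold is the Youden optimum.

    ``fit(X, y)`` takes AI scores (1-d, or a single column) and boolean
    cancer labels, builds the ROC curve, and stores the selected operating
    point; ``predict`` then applies ``score >= threshold_``.

    Parameters
    ----------
    tie_break : {"lowest", "highest"}
        Which threshold wins when several attain the maximal J.

    Attributes
    ----------
    curve_ : RocCurve
    threshold_ : float
    youden_j_, sensitivity_, specificity_ : float
    auc_ : float
    """

    def __init__(self, tie_break: str = "lowest"):
        self.tie_break = tie_break

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr.ravel()
        if arr.ndim != 1:
            raise ValidationError("X must be 1-d scores or a single column")
        return arr

    def fit(self, X, y):
        s = self._scores(X)
        curve = build_roc(s, y)
        result = youden_threshold(curve, tie_break=self.tie_break)
        self.curve_ = curve
        self.auc_ = auc(curve)
        self.threshold_ = result.threshold
        self.youden_j_ = result.youden_j
        self.sensitivity_ = result.sensitivity
        self.specificity_ = result.specificity
        self.result_ = result
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X):
        return self._scores(X) - self.threshold_

    def predict(self, X):
        return self._scores(X) >= self.threshold_
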