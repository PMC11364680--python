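"""Green/yellow/red triage of mammograms and contingency summaries.

A visit is **green** (negative) when its AI score is at or below the low
cut (1 by default — the score band the AI vendor itself reports as low
risk), **red** (positive) at or above the high cut (the Youden-selected
threshold), and **yellow** (flagged for human review) in between. A false
negative is a cancer visit not categorized red, i.e. green or yellow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .fixtures import DEFAULT_HIGH_CUT, DEFAULT_LOW_CUT
from .threshold import YoudenThresholdClassifier

CATEGORIES = ("green", "yellow", "red")
_MODES = ("screen_detected", "interval", "missed")


def _check_cuts(low_cut: float, high_cut: float) -> tuple[float, float]:
    low, high = float(low_cut), float(high_cut)
    if not low < high:
        raise ConfigurationError(f"low_cut must be below high_cut, got ({low}, {high})")
    return low, high


def categorize(ai_score, low_cut: float = DEFAULT_LOW_CUT,
               high_cut: float = DEFAULT_HIGH_CUT):
    """Map score(s) to triage categories.

    green iff score <= low_cut; red iff score >= high_cut; yellow otherwise.
    Scalar in, scalar out; array-like in, string array out.
    """
    low, high = _check_cuts(low_cut, high_cut)
    arr = np.asarray(ai_score, dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 100):
        raise ValidationError("ai_score must lie in [0, 100]")
    out = np.where(arr <= low, "green", np.where(arr >= high, "red", "yellow"))
    if np.isscalar(ai_score) or arr.ndim == 0:
        return str(out)
    return out


def category_codes(ai_score, low_cut: float = DEFAULT_LOW_CUT,
                   high_cut: float = DEFAULT_HIGH_CUT) -> np.ndarray:
    """Integer category codes (green=0, yellow=1, red=2) for fast tallies."""
    low, high = _check_cuts(low_cut, high_cut)
    arr = np.asarray(ai_score, dtype=float)
    return np.where(arr <= low, 0, np.where(arr >= high, 2, 1))


class TriageCategorizer(BaseEstimator, TransformerMixin):
    """Transformer mapping AI scores to green/yellow/red categories.

    Parameters
    ----------
    low_cut : float
        Score at/below which a visit is green (auto-negative).
    high_cut : float or "youden"
        Score at/above which a visit is red. With ``"youden"``, ``fit``
        requires cancer labels ``y`` and selects the cut maximizing
        Youden's J.

    Attributes
    ----------
    high_cut_ : float
        The resolved high cut after fitting.
    """

    def __init__(self, low_cut: float = DEFAULT_LOW_CUT,
                 high_cut=DEFAULT_HIGH_CUT):
        self.low_cut = low_cut
        self.high_cut = high_cut

    def fit(self, X, y=None):
        if isinstance(self.high_cut, str):
            if self.high_cut != "youden":
                raise ConfigurationError(f"unknown high_cut {self.high_cut!r}")
            if y is None:
                raise ConfigurationError('high_cut="youden" requires labels y')
            self.high_cut_ = YoudenThresholdClassifier().fit(X, y).threshold_
        else:
            self.high_cut_ = float(self.high_cut)
        _check_cuts(self.low_cut, self.high_cut_)
        return self

    def transform(self, X):
        if not hasattr(self, "high_cut_"):
            self.fit(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr.ravel()
        return categorize(arr, self.low_cut, self.high_cut_)


@dataclass(frozen=True)
class TriageTable:
    """Category counts by truth class and, for cancers, by detection mode."""

    by_truth: pd.DataFrame  # rows: non_cancer, cancer
    by_mode: pd.DataFrame  # rows: screen_detected, interval, missed
    low_cut: float
    high_cut: float

    def proportions(self) -> pd.DataFrame:
        """Row-normalized truth-class proportions (rows sum to 1)."""
        totals = self.by_truth.sum(axis=1)
        return self.by_truth.div(totals.replace(0, np.nan), axis=0)

    def mode_proportions(self) -> pd.DataFrame:
        totals = self.by_mode.sum(axis=1)
        return self.by_mode.div(totals.replace(0, np.nan), axis=0)


def build_triage_table(visits: pd.DataFrame, low_cut: float = DEFAULT_LOW_CUT,
                       high_cut: float = DEFAULT_HIGH_CUT) -> TriageTable:
    """Tally triage categories over a visit table.

    Detection-mode rows cover cancer visits only; an empty input yields an
    all-zero table.
    """
    low, high = _check_cuts(low_cut, high_cut)
    cats = pd.Categorical(
        categorize(visits["ai_score"].to_numpy(), low, high) if len(visits) else [],
        categories=list(CATEGORIES),
    )
    truth = np.where(visits["is_cancer_visit"].to_numpy(), "cancer", "non_cancer") \
        if len(visits) else np.array([], dtype=object)
    by_truth = (
        pd.crosstab(pd.Categorical(truth, categories=["non_cancer", "cancer"]), cats,
                    dropna=False)
        if len(visits)
        else pd.DataFrame(0, index=["non_cancer", "cancer"], columns=list(CATEGORIES))
    )
    by_truth = by_truth.reindex(index=["non_cancer", "cancer"],
                                columns=list(CATEGORIES), fill_value=0)
    by_truth.index.name = "stratum"

    cancer = visits[visits["is_cancer_visit"]] if len(visits) else visits
    if len(cancer):
        mode_cats = pd.Categorical(cancer["detection_mode"], categories=list(_MODES))
        ccats = pd.Categorical(
            categorize(cancer["ai_score"].to_numpy(), low, high),
            categories=list(CATEGORIES),
        )
        by_mode = pd.crosstab(mode_cats, ccats, dropna=False)
    else:
        by_mode = pd.DataFrame(0, index=list(_MODES), columns=list(CATEGORIES))
    by_mode = by_mode.reindex(index=list(_MODES), columns=list(CATEGORIES), fill_value=0)
    by_mode.index.name = "stratum"
    by_truth.columns = pd.Index(list(CATEGORIES), name="category")
    by_mode.columns = pd.Index(list(CATEGORIES), name="category")
    return TriageTable(by_truth=by_truth.astype(int), by_mode=by_mode.astype(int),
                       low_cut=low, high_cut=high)


def operating_metrics(table: TriageTable) -> dict:
    """Operating metrics of the red-vs-rest dichotomy.

    sensitivity = cancer red / cancer total;
    specificity = 1 - non-cancer red / non-cancer total;
    fp_rate_noncancer = non-cancer red share;
    fn_rate_cancer = share of cancers not red (green + yellow);
    detection_rate_<mode> = red share within each detection-mode row
    (NaN for an empty mode row).
    """
    n_nc = int(table.by_truth.loc["non_cancer"].sum())
    n_ca = int(table.by_truth.loc["cancer"].sum())
    if n_nc == 0 or n_ca == 0:
        raise UndefinedMetricError("both truth classes must be non-empty")
    fp = int(table.by_truth.loc["non_cancer", "red"])
    tp = int(table.by_truth.loc["cancer", "red"])
    metrics = {
        "sensitivity": tp / n_ca,
        "specificity": 1.0 - fp / n_nc,
        "fp_rate_noncancer": fp / n_nc,
        "fn_rate_cancer": (n_ca - tp) / n_ca,
    }
    for mode in _MODES:
        total = int(table.by_mode.loc[mode].sum())
        red = int(table.by_mode.loc[mode, "red"])
        metrics[f"detection_rate_{mode}"] = red / total if total else float("nan")
    return metrics
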