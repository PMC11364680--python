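"""In-repository fixtures: the published triage contingency table and
lead-time bins of the 10-year biennial screening cohort this package's
analyses are benchmarked against (4893 non-cancer and 105 cancer mammograms;
68 screen-detected / 29 interval / 8 missed cancers; 24 patients with an
AI-positive earlier visit).

The contingency fixture stores *counts* per (stratum x triage category).
:func:`table2_visits` expands those counts into individual synthetic visit
rows, assigning each row the midpoint score of its category's score
interval — downstream modules consume scores, and only the category matters
for every benchmarked computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import validate_visits

#: Default triage cut points: green <= 1, red >= 30.44 (Youden-selected).
DEFAULT_LOW_CUT = 1.0
DEFAULT_HIGH_CUT = 30.44

CATEGORIES = ("green", "yellow", "red")
_MODES = ("screen_detected", "interval", "missed")

#: Positive prior mammograms across the 24 patients with an earlier
#: AI-positive visit (11 patients carried a second positive prior).
N_PRIOR_POSITIVE_MAMMOGRAMS = 35


def _data_path(name: str):
    return resources.files("screentriage").joinpath("data", name)


@dataclass(frozen=True)
class Table2Fixture:
    """Triage-category counts by truth class and by detection mode."""

    by_truth: pd.DataFrame  # rows: non_cancer, cancer; cols: green, yellow, red
    by_mode: pd.DataFrame  # rows: screen_detected, interval, missed

    def __post_init__(self):
        for frame in (self.by_truth, self.by_mode):
            vals = frame.to_numpy()
            if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
                raise ValidationError("fixture counts must be nonnegative integers")
        if not self.by_mode.sum(axis=0).equals(self.by_truth.loc["cancer"]):
            raise ValidationError("detection-mode cells must sum to the cancer-row cells")


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged contingency fixture and check its margins."""
    raw = pd.read_csv(_data_path("table2.csv"), index_col="stratum")
    by_mode = raw.loc[list(_MODES)]
    by_truth = pd.DataFrame(
        [raw.loc["non_cancer"], by_mode.sum(axis=0).rename("cancer")]
    )
    by_truth.index = pd.Index(["non_cancer", "cancer"], name="stratum")
    fx = Table2Fixture(by_truth=by_truth, by_mode=by_mode)
    margins = {"non_cancer": 4893, "cancer": 105}
    for row, total in margins.items():
        if int(by_truth.loc[row].sum()) != total:
            raise ValidationError(f"fixture row {row!r} must sum to {total}")
    for row, total in zip(_MODES, (68, 29, 8)):
        if int(by_mode.loc[row].sum()) != total:
            raise ValidationError(f"fixture row {row!r} must sum to {total}")
    return fx


def load_lead_time_bins() -> dict[int, int]:
    """Lead-time bins (months -> patient count); counts sum to 24."""
    raw = pd.read_csv(_data_path("lead_time_bins.csv"))
    bins = dict(zip(raw["months"].astype(int), raw["patients"].astype(int)))
    if sum(bins.values()) != 24:
        raise ValidationError("lead-time bin counts must sum to 24")
    return bins


def category_midpoint(category: str, low_cut: float = DEFAULT_LOW_CUT,
                      high_cut: float = DEFAULT_HIGH_CUT) -> float:
    """Representative score inside a triage category's score interval."""
    if category == "green":
        return low_cut / 2.0
    if category == "yellow":
        return (low_cut + high_cut) / 2.0
    if category == "red":
        return (high_cut + 100.0) / 2.0
    raise ValidationError(f"unknown category {category!r}")


def table2_visits(low_cut: float = DEFAULT_LOW_CUT,
                  high_cut: float = DEFAULT_HIGH_CUT) -> pd.DataFrame:
    """Expand the contingency fixture into a 4998-row visit table.

    Every row carries its category's midpoint score, so re-categorizing at
    the same cuts reproduces the fixture counts exactly. Cancer rows carry
    their detection mode; screen-detected rows are reader-detected, interval
    and missed rows are not. All visits share one nominal month (the fixture
    has no per-visit dates); diagnosis dates follow the interval (<24
    months) and missed (1 month) definitions.
    """
    fx = load_table2_fixture()
    month = pd.Period("2015-01", freq="M")
    rows: list[dict] = []

    def add(n: int, category: str, mode: str):
        cancer = mode != "none"
        rdet = mode == "screen_detected"
        if mode == "none":
            diag = pd.NaT
        elif mode == "screen_detected":
            diag = month
        elif mode == "interval":
            diag = month + 12
        else:  # missed
            diag = month + 1
        score = category_midpoint(category, low_cut, high_cut)
        for _ in range(n):
            i = len(rows)
            rows.append(
                {
                    "visit_id": f"t2-{i:05d}",
                    "woman_id": f"t2w-{i:05d}",
                    "visit_date": month,
                    "ai_score": score,
                    "birads": 4 if rdet else 2,
                    "reader_detected": rdet,
                    "is_cancer_visit": cancer,
                    "detection_mode": mode,
                    "diagnosis_date": diag,
                }
            )

    for cat in CATEGORIES:
        add(int(fx.by_truth.loc["non_cancer", cat]), cat, "none")
    for mode in _MODES:
        for cat in CATEGORIES:
            add(int(fx.by_mode.loc[mode, cat]), cat, mode)
    return validate_visits(pd.DataFrame(rows))


def lead_time_visits(high_cut: float = DEFAULT_HIGH_CUT) -> pd.DataFrame:
    """Visit histories for the 24 patients with an AI-positive earlier visit.

    Each patient has a diagnosis visit and an earliest positive prior at her
    bin's lead time; the 11 patients with the deepest leads (>= 24 months)
    carry a second positive prior halfway to diagnosis, giving 35 positive
    prior mammograms in total. Only the bin structure is published; the
    within-patient placement of the extra priors is a synthetic convention
    that no computed quantity depends on.
    """
    bins = load_lead_time_bins()
    diag_month = pd.Period("2018-01", freq="M")
    pos_score = category_midpoint("red", high_cut=high_cut)

    leads: list[int] = []
    for months in sorted(bins):
        leads.extend([months] * bins[months])
    # deepest leads first -> deterministic choice of the 11 extra priors
    extra_flags = {i: False for i in range(len(leads))}
    for i in [k for k, _ in sorted(enumerate(leads), key=lambda kv: -kv[1])][:11]:
        extra_flags[i] = True

    rows: list[dict] = []
    for i, lead in enumerate(leads):
        woman = f"ltw-{i:02d}"
        visits = [(diag_month - lead, pos_score, False)]
        if extra_flags[i]:
            visits.append((diag_month - lead // 2, pos_score, False))
        visits.append((diag_month, pos_score, True))
        for j, (when, score, is_dx) in enumerate(visits):
            rows.append(
                {
                    "visit_id": f"lt-{i:02d}-{j}",
                    "woman_id": woman,
                    "visit_date": when,
                    "ai_score": score,
                    "birads": 5 if is_dx else 2,
                    "reader_detected": is_dx,
                    "is_cancer_visit": is_dx,
                    "detection_mode": "screen_detected" if is_dx else "none",
                    "diagnosis_date": diag_month if is_dx else pd.NaT,
                }
            )
    return validate_visits(pd.DataFrame(rows))
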