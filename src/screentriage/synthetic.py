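"""Synthetic screening cohorts with the statistical structure the analysis
assumes: biennial visits, a per-mammogram cancer rate of 5.7 per 1000,
AI-score category masses matching the benchmark contingency table, the
68/29/8 screen-detected/interval/missed split, and AI-positive earlier
visits for roughly 24/105 of cancer patients at published lead times.

Only category *masses* are constrained by the benchmark data; within each
category segment the score density is uniform — the least-informative
choice consistent with the published proportions that still leaves the
Youden optimum identifiable at the configured high cut (J rises through
the yellow segment and falls through the red one whenever the cancer class
puts more mass on red and less on yellow than the non-cancer class does).

All randomness derives from one root seed via ``numpy.random.SeedSequence``
stream-splitting (visit layout / cancer assignment / scores / detection
modes / prior-positive leads), so components are independently testable
and runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fixtures import DEFAULT_HIGH_CUT, DEFAULT_LOW_CUT
from .io import validate_visits

#: Category masses from the benchmark table: non-cancer 1928/2616/349 of
#: 4893; cancer 5/24/76 of 105.
NONCANCER_CATEGORY_PROBS = (1928 / 4893, 2616 / 4893, 349 / 4893)
CANCER_CATEGORY_PROBS = (5 / 105, 24 / 105, 76 / 105)
DETECTION_MODE_PROBS = (68 / 105, 29 / 105, 8 / 105)

#: Published lead-time bins, normalized to a sampling distribution.
DEFAULT_LEAD_TIME_DISTRIBUTION = {
    6: 3 / 24, 12: 3 / 24, 24: 10 / 24, 36: 4 / 24, 48: 1 / 24, 72: 3 / 24,
}


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    vec = tuple(float(p) for p in probs)
    if len(vec) != n:
        raise ConfigurationError(f"{name} must have {n} entries")
    if any(p < 0 for p in vec) or abs(sum(vec) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be a probability vector summing to 1")
    return vec


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults are the benchmark program's published conditions; ``seed`` is
    the single root seed for all streams.
    """

    n_women: int = 10_000
    rounds: int = 5
    cancer_rate: float = 0.0057
    category_probs_noncancer: tuple = NONCANCER_CATEGORY_PROBS
    category_probs_cancer: tuple = CANCER_CATEGORY_PROBS
    detection_mode_probs: tuple = DETECTION_MODE_PROBS
    prior_positive_fraction: float = 24 / 105
    lead_time_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEAD_TIME_DISTRIBUTION))
    low_cut: float = DEFAULT_LOW_CUT
    high_cut: float = DEFAULT_HIGH_CUT
    noncancer_recall_rate: float = 0.0
    screening_interval_months: int = 24
    start_month: str = "2009-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_women <= 0 or self.rounds <= 0:
            raise ConfigurationError("n_women and rounds must be positive")
        if not 0.0 <= self.cancer_rate < 1.0:
            raise ConfigurationError("cancer_rate must lie in [0, 1)")
        self.category_probs_noncancer = _check_probs(
            "category_probs_noncancer", self.category_probs_noncancer, 3)
        self.category_probs_cancer = _check_probs(
            "category_probs_cancer", self.category_probs_cancer, 3)
        self.detection_mode_probs = _check_probs(
            "detection_mode_probs", self.detection_mode_probs, 3)
        if not 0.0 <= self.prior_positive_fraction <= 1.0:
            raise ConfigurationError("prior_positive_fraction must lie in [0, 1]")
        lead_probs = _check_probs(
            "lead_time_distribution", list(self.lead_time_distribution.values()),
            len(self.lead_time_distribution))
        self.lead_time_distribution = dict(
            zip((int(m) for m in self.lead_time_distribution), lead_probs))
        if self.rounds < 2 and self.prior_positive_fraction > 0:
            raise ConfigurationError(
                "rounds must be >= 2 when prior_positive_fraction > 0 "
                "(no prior visit exists otherwise)")
        if not 0.0 <= self.noncancer_recall_rate <= 1.0:
            raise ConfigurationError("noncancer_recall_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreModel:
    """Piecewise-uniform score density over [0, 100].

    Mass ``probs = (green, yellow, red)`` is split at the two cut points;
    within each segment the density is uniform. Sampling then categorizing
    at the same cuts recovers ``probs`` in expectation.
    """

    probs: tuple
    low_cut: float
    high_cut: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cat = rng.choice(3, size=n, p=self.probs)
        u = rng.random(n)
        # open lower edge of the yellow segment: scores == low_cut are green
        y_lo = np.nextafter(self.low_cut, self.high_cut)
        out = np.empty(n)
        out[cat == 0] = u[cat == 0] * self.low_cut
        out[cat == 1] = y_lo + u[cat == 1] * (self.high_cut - y_lo)
        out[cat == 2] = self.high_cut + u[cat == 2] * (100.0 - self.high_cut)
        return out


def calibrate_score_model(category_probs, low_cut: float = DEFAULT_LOW_CUT,
                          high_cut: float = DEFAULT_HIGH_CUT) -> ScoreModel:
    """Build a :class:`ScoreModel` whose category masses are *category_probs*."""
    probs = _check_probs("category_probs", category_probs, 3)
    if not 0.0 < low_cut < high_cut < 100.0:
        raise ConfigurationError(
            f"cuts must satisfy 0 < low < high < 100, got ({low_cut}, {high_cut})")
    return ScoreModel(probs=probs, low_cut=float(low_cut), high_cut=float(high_cut))


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a validated visit table under *config*.

    Per woman: up to ``rounds`` visits spaced one screening interval apart
    (start month jittered within the first year). Cancer is assigned per
    visit at ``cancer_rate``; a woman exits screening after her cancer
    episode, so she contributes at most one. Cancer visits draw a detection
    mode; interval cancers are negative visits diagnosed within 24 months,
    missed cancers within 1 month, and ``reader_detected`` follows the
    mode. A ``prior_positive_fraction`` share of cancer patients receive an
    earlier AI-positive visit at a lead drawn from
    ``lead_time_distribution`` — inserted as an interim mammogram when the
    lead is off the biennial grid, clamped to the woman's first visit, and
    skipped (with the realized share reduced accordingly) for women
    diagnosed at their first round.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    r_layout, r_cancer, r_scores, r_modes, r_prior = (
        np.random.default_rng(child) for child in ss.spawn(5))

    start = pd.Period(cfg.start_month, freq="M")
    step = cfg.screening_interval_months
    offsets = r_layout.integers(0, 12, size=cfg.n_women)

    # first cancer visit per woman, if any; visits stop after it
    u = r_cancer.random((cfg.n_women, cfg.rounds))
    hit = u < cfg.cancer_rate
    any_cancer = hit.any(axis=1)
    first_hit = np.where(any_cancer, hit.argmax(axis=1), cfg.rounds - 1)
    n_visits = np.where(any_cancer, first_hit + 1, cfg.rounds)

    woman_idx = np.repeat(np.arange(cfg.n_women), n_visits)
    round_idx = np.concatenate([np.arange(k) for k in n_visits])
    n_total = woman_idx.size
    months = offsets[woman_idx] + step * round_idx
    is_cancer = any_cancer[woman_idx] & (round_idx == first_hit[woman_idx])

    nc_model = calibrate_score_model(cfg.category_probs_noncancer,
                                     cfg.low_cut, cfg.high_cut)
    ca_model = calibrate_score_model(cfg.category_probs_cancer,
                                     cfg.low_cut, cfg.high_cut)
    scores = np.empty(n_total)
    n_cancer = int(is_cancer.sum())
    scores[~is_cancer] = nc_model.sample(n_total - n_cancer, r_scores)
    scores[is_cancer] = ca_model.sample(n_cancer, r_scores)

    mode = np.full(n_total, "none", dtype=object)
    mode_code = r_modes.choice(3, size=n_cancer, p=cfg.detection_mode_probs)
    mode[is_cancer] = np.array(("screen_detected", "interval", "missed"))[mode_code]
    rdet = np.zeros(n_total, dtype=bool)
    rdet[is_cancer] = mode_code == 0
    if cfg.noncancer_recall_rate > 0:
        nc = ~is_cancer
        rdet[nc] = r_modes.random(n_total - n_cancer) < cfg.noncancer_recall_rate

    dates = start + months  # PeriodIndex
    diag = pd.Series(pd.NaT, index=pd.RangeIndex(n_total), dtype="period[M]")
    ci = np.flatnonzero(is_cancer)
    delay = np.zeros(n_cancer, dtype=int)
    delay[mode_code == 1] = r_modes.integers(1, 24, size=int((mode_code == 1).sum()))
    delay[mode_code == 2] = 1
    diag.iloc[ci] = dates[ci] + delay

    df = pd.DataFrame(
        {
            "visit_id": [f"s{w:06d}-{k}" for w, k in zip(woman_idx, round_idx)],
            "woman_id": [f"w{w:06d}" for w in woman_idx],
            "visit_date": pd.PeriodIndex(dates, freq="M"),
            "ai_score": scores,
            "birads": np.where(rdet, 4, 2),
            "reader_detected": rdet,
            "is_cancer_visit": is_cancer,
            "detection_mode": mode,
            "diagnosis_date": diag.values,
        }
    )

    extra = _prior_positive_rows(cfg, df, woman_idx, round_idx, ci, ca_model, r_prior)
    if extra is not None and len(extra):
        df = pd.concat([df, extra], ignore_index=True)
        df = df.sort_values(["woman_id", "visit_date"], kind="stable",
                            ignore_index=True)
    return validate_visits(df)


def _prior_positive_rows(cfg, df, woman_idx, round_idx, cancer_rows, ca_model,
                         rng) -> pd.DataFrame | None:
    """Earlier AI-positive visits for a share of cancer patients.

    Overrides the score of an existing prior visit when the drawn lead
    lands on the biennial grid; otherwise inserts an interim visit.
    """
    if cfg.prior_positive_fraction == 0 or cancer_rows.size == 0:
        return None
    leads_menu = np.array(sorted(cfg.lead_time_distribution))
    lead_p = np.array([cfg.lead_time_distribution[m] for m in leads_menu])

    marked = rng.random(cancer_rows.size) < cfg.prior_positive_fraction
    leads = rng.choice(leads_menu, size=cancer_rows.size, p=lead_p)
    red_lo = np.nextafter(cfg.high_cut, 100.0)

    rows = []
    for row, mark, lead in zip(cancer_rows, marked, leads):
        if not mark or round_idx[row] == 0:
            continue  # diagnosed at first round: no prior exists
        woman = woman_idx[row]
        diag_date = df.at[row, "visit_date"]
        first_date = diag_date - int(round_idx[row]) * cfg.screening_interval_months
        prior_date = max(diag_date - int(lead), first_date)
        score = float(red_lo + rng.random() * (100.0 - red_lo))
        months_back = (diag_date - prior_date).n
        if months_back % cfg.screening_interval_months == 0:
            # lands on an existing screening round: lift that visit's score
            k = int(round_idx[row]) - months_back // cfg.screening_interval_months
            target = row - (int(round_idx[row]) - k)
            df.at[target, "ai_score"] = score
        else:
            rows.append(
                {
                    "visit_id": f"s{woman:06d}-p",
                    "woman_id": f"w{woman:06d}",
                    "visit_date": prior_date,
                    "ai_score": score,
                    "birads": 2,
                    "reader_detected": False,
                    "is_cancer_visit": False,
                    "detection_mode": "none",
                    "diagnosis_date": pd.NaT,
                }
            )
    return pd.DataFrame(rows) if rows else None
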