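"""Reading-workflow simulation: double reading and three AI-assisted
scenarios, with workload, detection, recall, PPV1 and NPV accounting.

Scenarios
---------
bmsp
    The program's real workflow: two radiologists read every mammogram
    (third-reader arbitration excluded from workload, so workload is
    exactly twice the cohort size); detection and recall follow the
    recorded double-reading outcome.
s1
    One radiologist plus the AI as second reader: one read per visit; a
    visit is positive if the human recalls it or the AI scores it red.
s2
    As s1, plus a second human read of every yellow (flagged) visit.
s3
    AI triage: green visits are auto-negative and never read; yellow and
    red visits get one human read; red is escalated regardless.

Reader models
-------------
The benchmark data record only the final double-reading outcome, never
single-reader behavior, so human reads directed by the AI need an explicit
model. ``observed`` replays the recorded ``reader_detected`` flag;
``flag_perfect`` assumes the human, alerted by the AI flag, detects every
cancer in a yellow/red visit while non-cancer recalls still follow the
recorded flags. ``flag_perfect`` is the default for s2 and s3 (whose reads
are AI-directed); ``observed`` for bmsp and s1. With these defaults s1
detects 87 of the fixture's 105 cancers — the published 84 rests on an
unstated single-reader assumption and is deliberately not reproduced.

Recall (for PPV1) is the final positive call of the workflow: human recall
on the visits the scenario has read, plus AI-red auto-escalation where the
scenario defines it; a detected cancer is always recalled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_cohorts, simulated_cohort_size
from .errors import ConfigurationError, UndefinedMetricError
from .fixtures import DEFAULT_HIGH_CUT, DEFAULT_LOW_CUT
from .triage import CATEGORIES, category_codes

_GREEN, _YELLOW, _RED = 0, 1, 2


@dataclass(frozen=True)
class ReaderModel:
    """Human behavior on AI-directed reads.

    ``detect_probs``/``recall_probs`` give, per triage category, the
    probability that a human read detects a cancer visit / recalls a
    non-cancer visit; either is overridden by the recorded labels when the
    corresponding ``use_recorded_*`` flag is set.
    """

    name: str
    detect_probs: Mapping[str, float] = field(default_factory=dict)
    recall_probs: Mapping[str, float] = field(default_factory=dict)
    use_recorded_detection: bool = False
    use_recorded_recall: bool = False

    def __post_init__(self):
        for probs in (self.detect_probs, self.recall_probs):
            for cat, p in probs.items():
                if cat not in CATEGORIES:
                    raise ConfigurationError(f"unknown category {cat!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"probability out of [0, 1]: {p}")

    @classmethod
    def observed(cls) -> "ReaderModel":
        return cls(name="observed", use_recorded_detection=True,
                   use_recorded_recall=True)

    @classmethod
    def flag_perfect(cls) -> "ReaderModel":
        return cls(
            name="flag_perfect",
            detect_probs={"green": 0.0, "yellow": 1.0, "red": 1.0},
            use_recorded_recall=True,
        )

    def _eval(self, probs, use_recorded, code, rdet, rng):
        if use_recorded:
            return rdet.copy()
        p = np.array([probs.get(c, 0.0) for c in CATEGORIES])[code]
        if np.isin(p, (0.0, 1.0)).all():
            return p > 0.5
        if rng is None:
            raise ConfigurationError(
                "a stochastic reader model needs a seed (rng)")
        return rng.random(p.size) < p

    def human_detects(self, code, rdet, rng=None) -> np.ndarray:
        """Per-visit: would a human read detect this (cancer) visit?"""
        return self._eval(self.detect_probs, self.use_recorded_detection,
                          code, rdet, rng)

    def human_recalls(self, code, rdet, rng=None) -> np.ndarray:
        """Per-visit: would a human read recall this (non-cancer) visit?"""
        return self._eval(self.recall_probs, self.use_recorded_recall,
                          code, rdet, rng)

    @property
    def is_deterministic(self) -> bool:
        det = self.use_recorded_detection or all(
            p in (0.0, 1.0) for p in self.detect_probs.values())
        rec = self.use_recorded_recall or all(
            p in (0.0, 1.0) for p in self.recall_probs.values())
        return det and rec


READER_MODELS = {
    "observed": ReaderModel.observed,
    "flag_perfect": ReaderModel.flag_perfect,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A reading-workflow policy: reads per category plus rule name."""

    name: str
    reads_per_category: Mapping[str, int]
    description: str = ""

    def __post_init__(self):
        for cat in CATEGORIES:
            reads = self.reads_per_category.get(cat)
            if reads is None or not 0 <= reads <= 3:
                raise ConfigurationError(
                    f"reads for {cat!r} must be an integer in 0..3")

    def reads_vector(self) -> np.ndarray:
        return np.array([self.reads_per_category[c] for c in CATEGORIES])


SCENARIOS = {
    "bmsp": ScenarioSpec("bmsp", {"green": 2, "yellow": 2, "red": 2},
                         "double reading of every mammogram"),
    "s1": ScenarioSpec("s1", {"green": 1, "yellow": 1, "red": 1},
                       "single reader with AI as second reader"),
    "s2": ScenarioSpec("s2", {"green": 1, "yellow": 2, "red": 1},
                       "s1 plus a second human read of flagged visits"),
    "s3": ScenarioSpec("s3", {"green": 0, "yellow": 1, "red": 1},
                       "AI triage; green eliminated, yellow/red single-read"),
}

DEFAULT_READERS = {"bmsp": "observed", "s1": "observed",
                   "s2": "flag_perfect", "s3": "flag_perfect"}


@dataclass(frozen=True)
class ScenarioOutcome:
    """Workload and detection accounting of one scenario run."""

    scenario: str
    reader: str
    n_visits: int
    n_cancers: int
    workload: int
    detected_cancers: int
    missed_or_interval: int
    recalls: int
    cancers_recalled: int
    negatives: int


def _resolve(spec, reader):
    if isinstance(spec, str):
        if spec not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {spec!r}; choose from {sorted(SCENARIOS)}")
        spec = SCENARIOS[spec]
    elif spec.name not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {spec.name!r}")
    if reader is None:
        reader = READER_MODELS[DEFAULT_READERS[spec.name]]()
    elif isinstance(reader, str):
        if reader not in READER_MODELS:
            raise ConfigurationError(f"unknown reader model {reader!r}")
        reader = READER_MODELS[reader]()
    return spec, reader


def _scenario_flags(name, code, rdet, hd, hr):
    """Per-visit (detects-if-cancer, recalls) booleans for a scenario."""
    red = code == _RED
    yellow = code == _YELLOW
    if name == "bmsp":
        det, rec = rdet, rdet
    elif name == "s1":
        det = hd | red
        rec = hr | red
    elif name == "s2":
        # first read follows the recorded outcome; the reader model governs
        # the AI-directed second read of yellow visits
        det = rdet | red | (yellow & hd)
        rec = rdet | red | (yellow & hr)
    elif name == "s3":
        det = ((yellow | red) & hd) | red
        rec = red | (yellow & hr)
    else:  # pragma: no cover - guarded by _resolve
        raise ConfigurationError(f"unknown scenario {name!r}")
    return det, rec


def run_scenario(cohort: pd.DataFrame, spec, reader: Optional[ReaderModel] = None,
                 cuts: tuple[float, float] = (DEFAULT_LOW_CUT, DEFAULT_HIGH_CUT),
                 seed=None) -> ScenarioOutcome:
    """Simulate one reading workflow over a visit table.

    *spec* is a scenario name or :class:`ScenarioSpec`; *reader* defaults
    per scenario (see module docstring). *seed* is only needed for
    stochastic reader models.
    """
    spec, reader = _resolve(spec, reader)
    code = category_codes(cohort["ai_score"].to_numpy(), *cuts)
    cancer = cohort["is_cancer_visit"].to_numpy()
    rdet = cohort["reader_detected"].to_numpy()
    rng = np.random.default_rng(seed) if not reader.is_deterministic else None

    hd = reader.human_detects(code, rdet, rng)
    hr = reader.human_recalls(code, rdet, rng)
    det, rec = _scenario_flags(spec.name, code, rdet, hd, hr)

    workload = int(spec.reads_vector()[code].sum())
    detected = int(det[cancer].sum())
    cancers_recalled = detected  # a detected cancer is always recalled
    noncancer_recalls = int(rec[~cancer].sum())
    recalls = cancers_recalled + noncancer_recalls
    n = len(cohort)
    return ScenarioOutcome(
        scenario=spec.name,
        reader=reader.name,
        n_visits=n,
        n_cancers=int(cancer.sum()),
        workload=workload,
        detected_cancers=detected,
        missed_or_interval=int(cancer.sum()) - detected,
        recalls=recalls,
        cancers_recalled=cancers_recalled,
        negatives=n - recalls,
    )


def workload_reduction(outcome: ScenarioOutcome, baseline: ScenarioOutcome) -> float:
    """Percent workload saved relative to *baseline*."""
    if baseline.workload <= 0:
        raise UndefinedMetricError("baseline workload must be positive")
    return 100.0 * (1.0 - outcome.workload / baseline.workload)


def accuracy_increase(outcome: ScenarioOutcome, baseline: ScenarioOutcome,
                      n_cancers: int) -> float:
    """Extra cancers detected over *baseline*, as a percent of *n_cancers*."""
    if n_cancers <= 0:
        raise UndefinedMetricError("n_cancers must be positive")
    return 100.0 * (outcome.detected_cancers - baseline.detected_cancers) / n_cancers


def predictive_values(outcome: ScenarioOutcome) -> dict:
    """PPV1 (cancers among recalls) and NPV (non-cancers among negatives)."""
    if outcome.recalls <= 0:
        raise UndefinedMetricError("no recalls: PPV1 undefined")
    if outcome.negatives <= 0:
        raise UndefinedMetricError("no negatives: NPV undefined")
    missed = outcome.n_cancers - outcome.cancers_recalled
    return {
        "ppv1": outcome.cancers_recalled / outcome.recalls,
        "npv": (outcome.negatives - missed) / outcome.negatives,
    }


def bootstrap_scenarios(visits: pd.DataFrame, rate: float = 0.0057,
                        n_iter: int = 10_000, seed=None,
                        scenarios=("bmsp", "s1", "s2", "s3"), readers=None,
                        cuts: tuple[float, float] = (DEFAULT_LOW_CUT, DEFAULT_HIGH_CUT),
                        level: float = 0.95) -> pd.DataFrame:
    """Scenario accounting over a prevalence-matched bootstrap.

    Runs every requested scenario on each of *n_iter* resampled cohorts
    (the same cohort per iteration for all scenarios, so comparisons are
    paired) and aggregates to means and percentile intervals. Returns one
    row per scenario with workload, detection, recall, PPV1/NPV, and the
    workload reduction / accuracy increase against the bmsp baseline.

    Only deterministic reader models are supported here; the fixed cancer
    visits then contribute a constant per scenario and each iteration
    reduces to category tallies of the resampled non-cancer visits.
    """
    readers = dict(readers or {})
    names = list(dict.fromkeys(list(scenarios) + ["bmsp"]))
    resolved = {}
    for name in names:
        spec, reader = _resolve(name, readers.get(name))
        if not reader.is_deterministic:
            raise ConfigurationError(
                "bootstrap_scenarios supports deterministic reader models only")
        resolved[name] = (spec, reader)

    code = category_codes(visits["ai_score"].to_numpy(), *cuts)
    cancer = visits["is_cancer_visit"].to_numpy()
    rdet = visits["reader_detected"].to_numpy()
    nc = np.flatnonzero(~cancer)
    nc_code = code[nc]
    n_cancers = int(cancer.sum())
    size = simulated_cohort_size(n_cancers, rate)

    fixed = {}
    per_iter = {}
    for name, (spec, reader) in resolved.items():
        hd = reader.human_detects(code, rdet)
        hr = reader.human_recalls(code, rdet)
        det, rec = _scenario_flags(name, code, rdet, hd, hr)
        reads = spec.reads_vector()
        fixed[name] = {
            "detected": int(det[cancer].sum()),
            "cancer_reads": int(reads[code[cancer]].sum()),
            "nc_rec": rec[nc],  # per source non-cancer row
            "reads": reads,
        }
        per_iter[name] = {"workload": np.empty(n_iter), "recalls": np.empty(n_iter)}

    for cohort in bootstrap_cohorts(visits, rate=rate, n_iter=n_iter, seed=seed):
        # positions of the drawn rows within the non-cancer block
        local = np.searchsorted(nc, cohort.noncancer_indices)
        counts = np.bincount(nc_code[local], minlength=3)
        i = cohort.iteration
        for name, fx in fixed.items():
            per_iter[name]["workload"][i] = fx["cancer_reads"] + fx["reads"] @ counts
            per_iter[name]["recalls"][i] = fx["detected"] + fx["nc_rec"][local].sum()

    alpha = (1.0 - level) / 2.0
    base_w = per_iter["bmsp"]["workload"]
    rows = []
    for name in dict.fromkeys(scenarios):
        w = per_iter[name]["workload"]
        r = per_iter[name]["recalls"]
        detected = fixed[name]["detected"]
        ppv1 = np.divide(detected, r, out=np.full(n_iter, np.nan), where=r > 0)
        negatives = size - r
        npv = (negatives - (n_cancers - detected)) / negatives
        reduction = 100.0 * (1.0 - w / base_w)
        rows.append(
            {
                "scenario": name,
                "reader": resolved[name][1].name,
                "cohort_size": size,
                "n_cancers": n_cancers,
                "workload_mean": w.mean(),
                "workload_lo": np.quantile(w, alpha),
                "workload_hi": np.quantile(w, 1 - alpha),
                "detected_cancers": detected,
                "missed_or_interval": n_cancers - detected,
                "recalls_mean": r.mean(),
                "ppv1_mean": np.nanmean(ppv1),
                "npv_mean": npv.mean(),
                "workload_reduction_vs_bmsp_mean": reduction.mean(),
                "workload_reduction_vs_bmsp_lo": np.quantile(reduction, alpha),
                "workload_reduction_vs_bmsp_hi": np.quantile(reduction, 1 - alpha),
                "accuracy_increase_vs_bmsp": 100.0
                * (detected - fixed["bmsp"]["detected"]) / n_cancers,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
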