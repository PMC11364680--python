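"""End-to-end pipeline: load or generate a cohort, select cuts, tally the
triage table, bootstrap the reading scenarios, summarize lead times, and
write a reproducible report bundle.

Every report embeds the configuration, seed and package version, so any
number in it can be regenerated from the report alone; outputs contain no
timestamps, making repeated runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineStageError, ScreenTriageError
from .fixtures import DEFAULT_HIGH_CUT, DEFAULT_LOW_CUT, lead_time_visits, table2_visits
from .io import read_visits, write_visits
from .longitudinal import lead_time_summary
from .synthetic import SyntheticConfig, generate_cohort
from .threshold import YoudenThresholdClassifier, auc_bootstrap_ci
from .triage import build_triage_table, operating_metrics
from .workflow import bootstrap_scenarios

logger = logging.getLogger(__name__)

FIXTURES = {"table2": table2_visits, "leadtime": lead_time_visits}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    input_path: Optional[str] = None
    fixture: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    low_cut: float = DEFAULT_LOW_CUT
    high_cut: object = DEFAULT_HIGH_CUT  # float or "youden"
    scenarios: Sequence[str] = ("bmsp", "s1", "s2", "s3")
    readers: dict = field(default_factory=dict)
    rate: float = 0.0057
    n_iter: int = 10_000
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        sources = [s for s in (self.input_path, self.fixture, self.synthetic)
                   if s is not None]
        if len(sources) != 1:
            raise ConfigurationError(
                "exactly one input source (input_path | fixture | synthetic) required")
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ConfigurationError(
                f"unknown fixture {self.fixture!r}; choose from {sorted(FIXTURES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["scenarios"] = list(self.scenarios)
        return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ScreenTriageError as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return inner
    return wrap


def _load(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return read_visits(config.input_path)
    if config.fixture is not None:
        return FIXTURES[config.fixture]()
    return generate_cohort(config.synthetic)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write the report bundle.

    Returns the report dictionary; files go under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _yamlable(config.to_dict()),
    }

    logger.info("stage: load input")
    visits = _stage("load")(_load)(config)
    if config.synthetic is not None:
        write_visits(visits, outdir / "visits.csv")
    report["n_visits"] = len(visits)
    report["n_cancers"] = int(visits["is_cancer_visit"].sum())

    logger.info("stage: threshold selection")
    if config.high_cut == "youden":
        est = _stage("threshold")(YoudenThresholdClassifier().fit)(
            visits["ai_score"], visits["is_cancer_visit"])
        ci = _stage("threshold")(auc_bootstrap_ci)(
            visits["ai_score"], visits["is_cancer_visit"], seed=config.seed)
        high_cut = est.threshold_
        report["threshold"] = {
            "threshold": est.threshold_,
            "youden_j": est.youden_j_,
            "sensitivity": est.sensitivity_,
            "specificity": est.specificity_,
            "auc": est.auc_,
            "auc_ci_95": list(ci),
        }
    else:
        high_cut = float(config.high_cut)

    logger.info("stage: triage table")
    table = _stage("triage")(build_triage_table)(visits, config.low_cut, high_cut)
    table.by_truth.to_csv(outdir / "triage_table.csv")
    table.by_mode.to_csv(outdir / "triage_by_mode.csv")
    metrics = _stage("triage")(operating_metrics)(table)
    report["cuts"] = {"low": config.low_cut, "high": high_cut}
    report["operating_metrics"] = metrics

    if config.scenarios:
        logger.info("stage: workflow bootstrap (%d iterations)", config.n_iter)
        summary = _stage("scenarios")(bootstrap_scenarios)(
            visits, rate=config.rate, n_iter=config.n_iter, seed=config.seed,
            scenarios=tuple(config.scenarios), readers=config.readers,
            cuts=(config.low_cut, high_cut))
        summary.to_csv(outdir / "scenarios.csv")
        report["scenarios"] = {
            name: {k: _num(v) for k, v in row.items()}
            for name, row in summary.iterrows()
        }

    logger.info("stage: lead-time summary")
    if visits["is_cancer_visit"].any():
        lt = _stage("leadtime")(lead_time_summary)(visits, high_cut)
        lt.per_patient.to_csv(outdir / "leadtime.csv", index=False)
        report["lead_time"] = {
            "n_patients_earlier": lt.n_patients_earlier,
            "n_prior_positive_mammograms": lt.n_prior_positive_mammograms,
            "mean_months": _num(lt.mean_months),
            "sd_months": _num(lt.sd_months),
            "bin_counts": lt.bin_counts,
        }

    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(report), fh, sort_keys=True)
    return report


def _num(v):
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    return int(f) if f.is_integer() else f


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, float):
        return float(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj
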