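"""Prevalence-matching bootstrap: resample non-cancer visits with
replacement so the combined cohort attains a target cancer rate per
mammogram.

Cancer visits are held fixed — each appears exactly once per iteration and
is never resampled; only the non-cancer visits are drawn. The default unit
of resampling is the visit (mammogram); woman-level resampling, which keeps
each woman's visits together, is available as an option. Cohorts are
yielded as index sets into the source table, so iterating 10,000 times
never materializes more than one cohort (constant memory in ``n_iter``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError


def simulated_cohort_size(n_cancer: int, rate: float) -> int:
    """Total cohort size achieving *rate* cancers per mammogram.

    ``round(n_cancer / rate)``; the non-cancer draw count is the result
    minus ``n_cancer``.
    """
    if n_cancer <= 0:
        raise ConfigurationError("n_cancer must be positive")
    if not 0.0 < rate <= 1.0:
        raise ConfigurationError(f"rate must lie in (0, 1], got {rate}")
    return int(round(n_cancer / rate))


@dataclass(frozen=True)
class SimulatedCohort:
    """One prevalence-matched resample, as row positions into the source."""

    iteration: int
    seed: object
    cancer_indices: np.ndarray  # fixed, identical across iterations
    noncancer_indices: np.ndarray  # drawn with replacement

    @property
    def size(self) -> int:
        return int(self.cancer_indices.size + self.noncancer_indices.size)

    def to_frame(self, source: pd.DataFrame) -> pd.DataFrame:
        """Materialize the cohort as a visit table (cancers first)."""
        idx = np.concatenate([self.cancer_indices, self.noncancer_indices])
        return source.iloc[idx].reset_index(drop=True)


def bootstrap_cohorts(visits: pd.DataFrame, rate: float = 0.0057,
                      n_iter: int = 10_000, seed=None,
                      unit: str = "visit") -> Iterator[SimulatedCohort]:
    """Stream *n_iter* prevalence-matched cohorts from *visits*.

    Each iteration keeps every cancer visit once and draws
    ``size - n_cancer`` non-cancer visits uniformly with replacement
    (``unit="visit"``) or whole non-cancer women with replacement, trimmed
    to the target count (``unit="woman"``). Reproducible given *seed*.
    """
    if n_iter <= 0:
        raise ConfigurationError("n_iter must be positive")
    if unit not in ("visit", "woman"):
        raise ConfigurationError(f"unknown resampling unit {unit!r}")
    cancer_mask = visits["is_cancer_visit"].to_numpy()
    cancer_pos = np.flatnonzero(cancer_mask)
    noncancer_pos = np.flatnonzero(~cancer_mask)
    if cancer_pos.size == 0 or noncancer_pos.size == 0:
        raise DegenerateInputError("need at least one cancer and one non-cancer visit")
    size = simulated_cohort_size(cancer_pos.size, rate)
    n_draw = size - cancer_pos.size
    rng = np.random.default_rng(seed)

    if unit == "woman":
        women = visits["woman_id"].to_numpy()[noncancer_pos]
        groups = pd.Series(noncancer_pos).groupby(women, sort=True).apply(np.asarray)
        blocks = list(groups.to_numpy())

    for i in range(n_iter):
        if unit == "visit":
            draw = noncancer_pos[rng.integers(0, noncancer_pos.size, n_draw)]
        else:
            picked: list[np.ndarray] = []
            total = 0
            while total < n_draw:
                block = blocks[rng.integers(0, len(blocks))]
                picked.append(block)
                total += block.size
            draw = np.concatenate(picked)[:n_draw]
        yield SimulatedCohort(iteration=i, seed=seed, cancer_indices=cancer_pos,
                              noncancer_indices=draw)
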