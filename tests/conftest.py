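import numpy as np
import pandas as pd
import pytest

from screentriage.fixtures import lead_time_visits, table2_visits


@pytest.fixture(scope="session")
def fixture_visits() -> pd.DataFrame:
    """The benchmark contingency table expanded to 4998 visit rows."""
    return table2_visits()


@pytest.fixture(scope="session")
def leadtime_visits() -> pd.DataFrame:
    """Histories of the 24 patients with AI-positive earlier visits."""
    return lead_time_visits()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_visits(rng: np.random.Generator, n: int = 200,
                  cancer_frac: float = 0.2) -> pd.DataFrame:
    """A small random—but valid—visit table for tally/permutation tests."""
    cancer = rng.random(n) < cancer_frac
    modes = np.where(
        cancer,
        rng.choice(["screen_detected", "interval", "missed"], size=n),
        "none",
    )
    rdet = modes == "screen_detected"
    start = pd.Period("2010-01", freq="M")
    return pd.DataFrame(
        {
            "visit_id": [f"v{i}" for i in range(n)],
            "woman_id": [f"w{i}" for i in range(n)],
            "visit_date": [start + int(m) for m in rng.integers(0, 120, n)],
            "ai_score": rng.random(n) * 100,
            "birads": np.where(rdet, 4, 2),
            "reader_detected": rdet,
            "is_cancer_visit": cancer,
            "detection_mode": modes,
        }
    )
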