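import numpy as np
import pandas as pd
import pytest

from scanwear.config import CohortConfig
from scanwear.cohort import simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (9 children, 36 adults, 180 days)."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for pipeline plumbing tests."""
    cfg = CohortConfig(n_children=3, n_adults=6, horizon_days=60,
                       prop_with_scans=0.0, seed=3)
    return simulate_cohort(cfg)


def make_event_dataset(shape: str, n: int = 4320, noise_sd: float = 0.25,
                       amplitude: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Single-feature scan-event dataset with a planted feature-response shape.

    Response is minutes-to-scan, one row per minute of a 3-day window; the
    feature follows the planted smooth g(u) of scan proximity u = 1 - t/w
    plus Gaussian noise.
    """
    from scanwear.cohort import prescan_effect

    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, float(n), n)  # minutes to scan
    g = prescan_effect(t, shape, amplitude, float(n))
    x = g + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"time_to_scan": t, "feature": x})
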