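import numpy as np
import pandas as pd
import pytest

from fhbrisk import CohortConfig, simulate_cohort
from fhbrisk.experiments import RECOVERY_OFFSET, recovery_config
from fhbrisk.pseudotime import make_pseudo_time


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Registry-like cohort, small enough for fast unit tests."""
    return simulate_cohort(CohortConfig(n_subjects=3000, seed=11))


@pytest.fixture(scope="session")
def interval_rich_cohort() -> pd.DataFrame:
    """Cohort with inflated CRC incidence so interval cancers are plentiful."""
    cfg = CohortConfig(
        n_subjects=8000,
        n_rounds=3,
        incidence_rates={"nada": 1.5e-3, "ada": 6e-4, "crc": 1e-2},
        interval_cancer_fraction=0.5,
        seed=21,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_frame() -> pd.DataFrame:
    """Correctly-specified (zero-free, negligible-offset) pseudo-time frame."""
    records = simulate_cohort(recovery_config(seed=5, n_subjects=12_000))
    records = records.dropna(subset=["fhb_std"])  # drop the few interval cancers
    return make_pseudo_time(records, offset=RECOVERY_OFFSET, missing="error")


def brute_force_quantile(values: np.ndarray, p: float) -> float:
    """Left-continuous empirical quantile: smallest x with F(x) >= p."""
    srt = np.sort(np.asarray(values, dtype=float))
    idx = int(np.ceil(p * len(srt))) - 1
    return float(srt[max(idx, 0)])
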