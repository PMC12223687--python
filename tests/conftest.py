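import numpy as np
import pandas as pd
import pytest

from labscreen import default_cohort_config, default_ranges, generate_cohort


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()


@pytest.fixture(scope="session")
def small_cohort():
    """80-patient, two-parameter extract reused across read-only tests."""
    cfg = default_cohort_config(
        n_patients=80, seed=11, parameters=["hemoglobin", "creatinine"]
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_series(values, start="2015-01-01", step_days=30):
    """(value, date) series with regular spacing, for window tests."""
    dates = pd.date_range(start, periods=len(values), freq=f"{step_days}D").date
    return list(zip([float(v) for v in values], dates))
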