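import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fwave as fw

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 2000.0


@pytest.fixture(scope="session")
def clean_record():
    """Ventricle- and disturbance-free 20-s AF record, 0.05 mV f-waves."""
    params = fw.preset_params("clean", seed=11, duration_s=20.0)
    return fw.simulate_af_ecg(params)


@pytest.fixture(scope="session")
def typical_record():
    """Full composite 60-s AF record (QRS 1.0 mV, f-waves 0.05 mV)."""
    params = fw.preset_params("typical", seed=7, duration_s=60.0)
    return fw.simulate_af_ecg(params)


@pytest.fixture(scope="session")
def small_cohort():
    return fw.simulate_cohort(fw.CohortSimParams(seed=3))


def make_cohort_frame(rows):
    """Hand-built minimal cohort DataFrame from (id, outcome, base, end)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "outcome": outcome,
                "fwa_II_baseline": base,
                "fwa_II_endwpvi": end,
            }
            for pid, outcome, base, end in rows
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
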