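import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from circaphase.core import TimeSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from circaphase.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Five subjects with fixed seed, shared across tests."""
    return generate_cohort(5, 7, default_config)


@pytest.fixture
def minute_series():
    """Factory for a minute-level TimeSeries from decimal-hour values."""

    def make(values, start="2024-01-01 00:00", unit="degC", subject="T1",
             channel="core_temp"):
        idx = pd.date_range(start, periods=len(values), freq="min")
        return TimeSeries(idx, np.asarray(values, dtype=float), unit, subject, channel)

    return make


def truth_frame(n, seed, config=None):
    """Cohort ground truth renamed to the phase-table column vocabulary."""
    from circaphase.simulate import truths_to_frame

    df = truths_to_frame(generate_cohort(n, seed, config))
    return df.rename(columns={
        "true_core_bathyphase": "core_bathyphase",
        "true_core_acrophase": "core_acrophase",
        "true_center_of_rest": "center_of_rest",
        "true_chest_bathyphase": "chest_bathyphase",
        "true_chest_acrophase": "chest_acrophase",
        "true_dlmo": "dlmo",
    })
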