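import numpy as np
import pandas as pd
import pytest

from actirhythm.io import EpochSeries


def make_series(counts, start="2020-01-06 00:00", pid="T001") -> EpochSeries:
    return EpochSeries(
        participant_id=pid,
        start_time=pd.Timestamp(start),
        counts=np.asarray(counts, dtype=float),
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated 12-participant cohort shared across tests."""
    from actirhythm.simulate import SimulationConfig, simulate_cohort

    config = SimulationConfig(n_participants=12, days=7, seed=42)
    return simulate_cohort(config)
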