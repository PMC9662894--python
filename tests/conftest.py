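import numpy as np
import pandas as pd
import pytest

from joinpoint_survival import (
    SimulationConfig,
    SurvivalTable,
    fit_fixed_joinpoints,
    simulate_table,
)

BASELINE = [0.80, 0.90, 0.93, 0.95, 0.96]


@pytest.fixture(scope="session")
def one_jp_config():
    """Moderate-size one-joinpoint truth used across modules."""
    return SimulationConfig(
        year_range=(1990, 2009),
        n_intervals=5,
        cohort_size=2000,
        baseline_interval_survival=BASELINE,
        beta=-0.02,
        deltas=(-0.06,),
        taus=(2000,),
        seed=20090,
    )


@pytest.fixture(scope="session")
def one_jp_table(one_jp_config):
    return simulate_table(one_jp_config)


@pytest.fixture(scope="session")
def one_jp_fit(one_jp_table):
    """Fit at the true joinpoint (fixed taus)."""
    return fit_fixed_joinpoints(one_jp_table, taus=(2000,))


@pytest.fixture(scope="session")
def flat_config():
    """No trend, no joinpoint."""
    return SimulationConfig(
        year_range=(1990, 2009),
        n_intervals=5,
        cohort_size=2000,
        baseline_interval_survival=BASELINE,
        beta=0.0,
        seed=41,
    )


@pytest.fixture(scope="session")
def flat_table(flat_config):
    return simulate_table(flat_config)


@pytest.fixture()
def toy_frame():
    """Minimal well-formed 2-year x 2-interval relative-survival table."""
    return pd.DataFrame({
        "Year": [2000, 2000, 2001, 2001],
        "Interval": [1, 2, 1, 2],
        "Alive_at_Start": [100, 80, 120, 100],
        "Lost_to_Followup": [4, 2, 6, 4],
        "Died": [16, 10, 14, 12],
        "Expected_Survival_Interval": [0.97, 0.96, 0.97, 0.96],
    })


@pytest.fixture()
def toy_table(toy_frame):
    return SurvivalTable(toy_frame, mode="relative")
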