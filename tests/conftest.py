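import numpy as np
import pandas as pd
import pytest

from posturo import (
    COPTrajectory,
    StudyDesign,
    simulate_study,
    summarize_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_study():
    """One default simulated study (960 trial rows) shared across tests."""
    table, truth = simulate_study(StudyDesign(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def default_summaries(default_study):
    table, _ = default_study
    return summarize_table(table)


def make_traj(x, y, fs=50.0, load=64.5):
    x = np.asarray(x, dtype=float)
    return COPTrajectory(
        fs=fs,
        x=x,
        y=np.asarray(y, dtype=float),
        total_load=np.full(x.size, load),
    )


@pytest.fixture
def circle_traj():
    """Radius-5 circle sampled at 1000 points over one revolution."""
    th = np.linspace(0, 2 * np.pi, 1001)
    return make_traj(5 * np.cos(th), 5 * np.sin(th), fs=50.0)
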