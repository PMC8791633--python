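import numpy as np
import pytest

import optoplace as op


@pytest.fixture(scope="session")
def config():
    return op.AnalysisConfig()


@pytest.fixture(scope="session")
def maze():
    return op.MazeGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """Three tuned + two weak cells with short sessions, shared across tests."""
    spec = op.default_cohort_spec(seed=11)
    spec.classes[0].n_cells = 3
    spec.classes[1].n_cells = 2
    spec.session_duration_s = 120.0
    return op.generate_cohort(spec)


@pytest.fixture(scope="session")
def trajectory(maze):
    return op.simulate_trajectory(maze, duration_s=300.0, tracking_rate_Hz=25.0, seed=3)


def make_pulses(n=50, rate_hz=1.0, start=10.0, power=0.5, duration_ms=1.0):
    onsets = start + np.arange(n) / rate_hz
    return op.LightPulseTrain(onsets=onsets, duration_ms=duration_ms,
                              power_mW=power, train_frequency_Hz=rate_hz)
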