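import numpy as np
import pytest

from optophysio import (
    HeartSimParams,
    TimeSeries,
    opsin_presets,
    pulse_schedule,
    simulate_heart_trial,
    simulate_photostate,
)

FPS = 67.0


@pytest.fixture(scope="session")
def dark_photostate():
    """Zero active fraction over 30 s at the camera rate (no stimulus)."""
    t = np.arange(0.0, 30.0 + 0.5 / FPS, 1.0 / FPS)
    return TimeSeries(t, np.zeros_like(t))


@pytest.fixture(scope="session")
def mosopn3_photostate():
    """Active fraction for the default green-pulse scenario (onset 5 s)."""
    sched = pulse_schedule("mosopn3", onset_s=5.0)
    return simulate_photostate(opsin_presets()["mosopn3"], sched, 30.0, 1.0 / FPS)


@pytest.fixture(scope="session")
def mosopn3_schedule():
    return pulse_schedule("mosopn3", onset_s=5.0)


@pytest.fixture()
def plain_heart_trial(dark_photostate):
    """Noiseless 150 bpm trial with no stimulus: 75 beats over 30 s."""
    hp = HeartSimParams(noise_sd=0.0)
    return simulate_heart_trial(hp, dark_photostate, 30.0, seed=3)
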