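import numpy as np
import pytest

from uwbmotion import RadarFrameSeries
from uwbmotion.phantom import Scenario, make_session_scenario


@pytest.fixture
def quiet_scenario():
    """No movement at all: zero noise, zero respiration, no events."""
    return Scenario(duration_s=20.0, noise_sigma=0.0,
                    respiration_amplitude=0.0, seed=0)


@pytest.fixture
def session_scenario():
    """Canonical left-dominant (3:1) 60 s monitoring session."""
    return make_session_scenario(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(frames, frame_rate=20.0, side="left"):
    return RadarFrameSeries(frames=np.asarray(frames, dtype=float),
                            frame_rate=frame_rate, side=side)


@pytest.fixture
def series_factory():
    return make_series
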