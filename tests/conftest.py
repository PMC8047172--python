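import numpy as np
import pytest

from batgaze.beam import BeamModel
from batgaze.geometry import Condition, default_mic_array, default_room
from batgaze.localize import analyze_flight
from batgaze.propagation import Environment
from batgaze.simulate import simulate_flight


@pytest.fixture(scope="session")
def room_right():
    return default_room(Condition.RIGHT_TURN)


@pytest.fixture(scope="session")
def room_straight():
    return default_room(Condition.STRAIGHT)


@pytest.fixture(scope="session")
def mics():
    return default_mic_array()


@pytest.fixture(scope="session")
def beam():
    return BeamModel.calibrated()


@pytest.fixture(scope="session")
def rt_flight(room_right, mics):
    """One simulated right-turn flight shared across detector/localizer tests."""
    wave, truth = simulate_flight(room_right, mics, seed=1234)
    return wave, truth


@pytest.fixture(scope="session")
def rt_quiet_flight(room_right, mics):
    """Near-noiseless render for exact count/onset checks."""
    wave, truth = simulate_flight(room_right, mics, seed=1234,
                                  env=Environment(noise_db=-120.0))
    return wave, truth


@pytest.fixture(scope="session")
def rt_calls(rt_flight, room_right, mics):
    wave, _truth = rt_flight
    return analyze_flight(wave, mics, room_right)


def match_truth(calls, truth, tol_s=0.005):
    """Pair reconstructed calls with ground truth by emission time."""
    gt = truth.calls if hasattr(truth, "calls") else truth
    pairs = []
    for r in calls.itertuples():
        i = (gt["emission_time_s"] - r.emission_time_s).abs().idxmin()
        g = gt.loc[i]
        if abs(g.emission_time_s - r.emission_time_s) < tol_s:
            pairs.append((r, g))
    return pairs
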