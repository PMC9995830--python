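import numpy as np
import pytest

from woolsim import BehaviorConfig, ObserverConfig


@pytest.fixture
def default_config():
    return BehaviorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def walk_heavy_config():
    """A flock that walks almost constantly in short bouts: every sheep
    presents many classification opportunities within a short session."""
    return BehaviorConfig(
        budget_graze=0.05,
        budget_stand=0.05,
        budget_walk=0.9,
        mean_bout_graze=5.0,
        mean_bout_stand=5.0,
        mean_bout_walk=5.0,
        session_length=300.0,
        p_lame=1.0,
    )


@pytest.fixture
def perfect_observer():
    return ObserverConfig(sensitivity=1.0, false_alarm=0.0, attention=24)
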