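import pytest

from hatchtrack.core import StageLabel, TrackerConfig
from hatchtrack.synthetic import RhythmPreset, simulate_colony


@pytest.fixture
def cfg():
    return TrackerConfig()


@pytest.fixture
def pupae_cfg():
    """Circadian-experiment configuration: track pupal classes only."""
    return TrackerConfig(tracked_classes={StageLabel.FULL_PUPA, StageLabel.EMPTY_PUPA})


@pytest.fixture(scope="session")
def mini_preset():
    """A shortened rhythmic recording (7 days) for fast unit tests."""
    return RhythmPreset(name="mini", period_h=24.0, amplitude=0.8, onset_h=48.0, duration_h=168.0)


@pytest.fixture(scope="session")
def mini_colony(mini_preset):
    """Small noise-free colony: 8 animals over 1008 frames."""
    return simulate_colony(
        mini_preset,
        rng_seed=11,
        n_animals=8,
        pupal_duration_h=24.0,
        larval_duration_h=6.0,
        adult_lifetime_h=6.0,
    )
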