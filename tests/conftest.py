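import pytest

from tonetrain.battery import simulate_battery
from tonetrain.design import DesignConfig


@pytest.fixture(scope="session")
def small_config() -> DesignConfig:
    """Scaled-down design: 12 subjects, short tasks, full structure."""
    return DesignConfig(
        n_per_condition=4,
        trials_per_training_session=24,
        oddity_trials=24,
        picture_id_trials=24,
        repetition_words=12,
        naming_pictures=12,
        aptitude_trials=24,
        continuum_repetitions=10,
    )


@pytest.fixture(scope="session")
def small_battery(small_config):
    """One simulated battery dataset shared by read-only tests."""
    return simulate_battery(small_config, seed=11)
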