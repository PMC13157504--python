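import numpy as np
import pytest

from statewave.synthetic import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session shared across tests."""
    cfg = SimulationConfig(
        n_trials=120,
        trial_duration=1.2,
        pre_stim=0.4,
        n_channels=4,
        probe_fraction=0.25,
        seed=42,
    )
    return generate_session(cfg, return_components=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
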