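import numpy as np
import pytest

from eegvigil import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def short_session():
    """A 300 s synthetic session with a strong theta signature."""
    cfg = SimulationConfig(duration_s=300.0, seed=11)
    return cfg, simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
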