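import numpy as np
import pytest

from plastisim import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Small, fast scenario for engine-level tests."""
    return SimulationConfig.from_values(K=200, t_max=20, psi=1.0, seed=42)
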