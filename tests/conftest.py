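import numpy as np
import pytest

from glomnet.network import NetworkConfig
from glomnet.stimuli import generate_odor_panel


@pytest.fixture(scope="session")
def default_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def reference_panel():
    """The canonical shipped 6x16 odor panel (seed 1)."""
    return generate_odor_panel(6, 16, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
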