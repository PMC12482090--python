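import numpy as np
import pytest

from likertsim.experiments import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def cfg_default():
    """Package-default study conditions (seed included)."""
    return SimulationConfig()
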