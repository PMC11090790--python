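import numpy as np
import pytest

from melreg.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return SimulationConfig(
        seed=7, n_genes=300, n_peaks=300, n_cells=100, n_cells_spatial=400
    )


@pytest.fixture
def default_config():
    """The generator's study conditions."""
    return SimulationConfig(seed=7)
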