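import numpy as np
import pytest

from mobdpcr import SimConfig, default_assay


@pytest.fixture(scope="session")
def assay():
    return default_assay()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def novol_config():
    """Chip config with no volume variability (pure Poisson occupancy)."""
    return SimConfig(volume_cv=0.0)
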