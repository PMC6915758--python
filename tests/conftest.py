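import numpy as np
import pytest

from depwell import FrequencyGrid, Medium
from depwell.synthetic import preset


@pytest.fixture(scope="session")
def jurkat():
    """Jurkat cell and its 10 mS/m measurement medium."""
    return preset("jurkat_3dep")


@pytest.fixture(scope="session")
def platelet_800():
    """Platelet in 800 mS/m medium (high-conductivity parameter set)."""
    return preset("platelet_hiconf_800")


@pytest.fixture(scope="session")
def grid20():
    """The instrument's standard 20-point, 1 kHz-45 MHz grid."""
    return FrequencyGrid.log_spaced(1e3, 45e6, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
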