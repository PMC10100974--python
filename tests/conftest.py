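import numpy as np
import pytest

from gutiron.growth import GompertzParams
from gutiron.synthetic import SimConfig


@pytest.fixture
def rich_params() -> GompertzParams:
    """Rich-medium triplicate fit: A = 1.46 au, mu_m = 0.260 au/h, lag 4.94 h."""
    return GompertzParams(A=1.46, mu_m=0.260, lam=4.94)


@pytest.fixture
def times_30h() -> np.ndarray:
    return np.arange(0.0, 30.5, 0.5)


@pytest.fixture
def quiet_config() -> SimConfig:
    return SimConfig(seed=11).zero_noise()
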