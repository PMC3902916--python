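import numpy as np
import pytest

from sigmakin.grid import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
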