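import numpy as np
import pytest

from ybrachy import yb169_source, yb169_spectrum


@pytest.fixture(scope="session")
def spectrum():
    return yb169_spectrum()


@pytest.fixture(scope="session")
def source():
    return yb169_source()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
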