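import numpy as np
import pytest

from symte.series import BinarySeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bs(symbols, start="1999-01", label=""):
    """Shorthand BinarySeries constructor for tests."""
    return BinarySeries(np.asarray(symbols, dtype=np.int8), start, label)


@pytest.fixture
def make_binary():
    return bs
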