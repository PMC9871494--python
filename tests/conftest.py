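import numpy as np
import pytest

from isopascal import default_registry, load_isotope_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def isotope_table():
    return load_isotope_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
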