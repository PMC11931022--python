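import numpy as np
import pytest

from wmfcs.parcellation import default_scheme, generic_scheme


@pytest.fixture(scope="session")
def scheme164():
    return default_scheme()


@pytest.fixture(scope="session")
def small_scheme():
    """A 20-region scheme (8 cortical + 4 subcortical + 8 WM) for fast tests."""
    return generic_scheme(8, 4, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
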