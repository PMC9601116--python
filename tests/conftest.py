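import numpy as np
import pytest

from politeia import params_from_asymmetries


@pytest.fixture(scope="session")
def symmetric_params():
    """Fully symmetric couplings: both asymmetries vanish, tau = 1."""
    return params_from_asymmetries(0.0, 0.0)


@pytest.fixture(scope="session")
def asym_params():
    """A generic asymmetric parameter point used across modules."""
    return params_from_asymmetries(0.2, 0.03)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
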