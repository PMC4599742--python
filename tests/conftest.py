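import numpy as np
import pytest

from rbfcme import ToggleParams, build_toggle2d
from rbfcme.io import make_fixture


@pytest.fixture(scope="session")
def birth_death_system():
    """Small birth-death chain with its truncated-Poisson reference."""
    return make_fixture("birth_death", {"lam": 5.0, "mu": 1.0, "N": 30})


@pytest.fixture(scope="session")
def toggle_network():
    return build_toggle2d(ToggleParams.symmetric_bistable())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
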