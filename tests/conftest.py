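import numpy as np
import pytest

from mtflare.energetics import (InteractionParams, MechanicalParams,
                                RingParams)


@pytest.fixture(scope="session")
def mech():
    return MechanicalParams()


@pytest.fixture(scope="session")
def inter():
    return InteractionParams()


@pytest.fixture(scope="session")
def ring_params():
    return RingParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
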