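import numpy as np
import pytest

from springnet.params import ModelParams


@pytest.fixture(scope="session")
def params_super():
    """1D parameter set on the supercritical side of the type boundary."""
    return ModelParams(D=0.003, ell=0.4725)


@pytest.fixture(scope="session")
def params_sub():
    """1D parameter set on the subcritical side."""
    return ModelParams(D=0.0338, ell=0.3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
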