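import numpy as np
import pytest

from acmseg import ModelParams, default_params
from acmseg.phantoms import standard_suite


@pytest.fixture(scope="session")
def suite():
    """Standard phantom set as a name -> (image, truth) mapping."""
    return {name: (image, truth) for name, image, truth in standard_suite()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def small_params():
    """Parameters sized for 8x8 finite-difference oracle tests."""
    return ModelParams(sigma=1.5, window=3, epsilon=1.0)
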