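import numpy as np
import pytest

from bogeom.internal_coords import formaldehyde_like_space
from bogeom.pes_models import (
    benchmark_2d_model,
    benchmark_2d_space,
    benchmark_6d_model,
    benchmark_6d_space,
)


@pytest.fixture(scope="session")
def model2d():
    return benchmark_2d_model()


@pytest.fixture(scope="session")
def space2d():
    return benchmark_2d_space()


@pytest.fixture(scope="session")
def model6d():
    return benchmark_6d_model()


@pytest.fixture(scope="session")
def space6d():
    return benchmark_6d_space()


@pytest.fixture(scope="session")
def h2co_space():
    return formaldehyde_like_space()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
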