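import numpy as np
import pytest

from combpat.acoustic import AcousticMedium, SensorResponse, linear_array_geometry
from combpat.comb import CombSpec
from combpat.ring_array import assign_resonances


@pytest.fixture(scope="session")
def default_comb_spec():
    return CombSpec()


@pytest.fixture(scope="session")
def array3():
    """Three rings at the standard 1.66-GHz spacing inside the 40-GHz band."""
    return assign_resonances(3, 1.66e9, (-20e9, 20e9))


@pytest.fixture(scope="session")
def array15():
    return assign_resonances(15, 1.66e9, (-20e9, 20e9))


@pytest.fixture(scope="session")
def medium():
    return AcousticMedium()


@pytest.fixture(scope="session")
def response():
    return SensorResponse()


@pytest.fixture(scope="session")
def static_array_geometry():
    return linear_array_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
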