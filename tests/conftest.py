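import numpy as np
import pytest

from fiberlysis import RateSet, SimConfig, build_cross_section


@pytest.fixture(scope="session")
def cs7():
    return build_cross_section(7)


@pytest.fixture(scope="session")
def cs3():
    return build_cross_section(3)


@pytest.fixture
def baseline():
    return RateSet()


@pytest.fixture
def default_config():
    return SimConfig()


@pytest.fixture
def rng():
    return np.random.RandomState(12345)
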