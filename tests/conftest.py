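import numpy as np
import pytest

from sga_mediation import Variant


@pytest.fixture
def rng():
    return np.random.default_rng(20171211)


@pytest.fixture(scope="session")
def linear_homo():
    return Variant("linear", "homoskedastic")


@pytest.fixture(scope="session")
def cubic_homo():
    return Variant("cubic", "homoskedastic")


@pytest.fixture(scope="session")
def linear_het():
    return Variant("linear", "ga_specific")
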