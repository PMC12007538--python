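import numpy as np
import pytest

from smsfus import ProbeGeometry, build_schedule, make_atlas


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def schedule(probe):
    return build_schedule(probe, 4)


@pytest.fixture(scope="session")
def atlas():
    """Small bilateral label volume with its region table."""
    return make_atlas((16, 4, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
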