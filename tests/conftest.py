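import numpy as np
import pytest

from cocoanir import make_fixture


@pytest.fixture(scope="session")
def fixture56():
    """The default simulated study: 56 samples, both instruments/modes."""
    return make_fixture()


@pytest.fixture(scope="session")
def ground_portable(fixture56):
    return fixture56.get("portable", "ground")


@pytest.fixture(scope="session")
def ground_benchtop(fixture56):
    return fixture56.get("benchtop", "ground")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
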