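import numpy as np
import pytest

from saftgmie import GammaMieEoS, default_db, make_fixture, water


@pytest.fixture(scope="session")
def db():
    return default_db()


@pytest.fixture(scope="session")
def water_eos():
    return GammaMieEoS([water()])


@pytest.fixture(scope="session")
def lj_eos():
    fx = make_fixture("lj-like-mie")
    return GammaMieEoS(fx["components"], groups=fx["groups"], db=fx["db"])


@pytest.fixture(scope="session")
def hs_eos():
    fx = make_fixture("hard-sphere")
    return GammaMieEoS(fx["components"], groups=fx["groups"], db=fx["db"])


@pytest.fixture(scope="session")
def ideal_eos():
    fx = make_fixture("ideal-gas")
    return GammaMieEoS(fx["components"], groups=fx["groups"], db=fx["db"])


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        yield
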