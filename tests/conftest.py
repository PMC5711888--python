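import pytest

from angionet.angiomodel import load_model, sweep_environments
from angionet.netcore import parse_network


@pytest.fixture(scope="session")
def model():
    net, meta = load_model()
    return net, meta


@pytest.fixture(scope="session")
def net(model):
    return model[0]


@pytest.fixture(scope="session")
def meta(model):
    return model[1]


@pytest.fixture(scope="session")
def wild_type_sweep(net):
    """The full 2^16 wild-type environment sweep (computed once per run)."""
    return sweep_environments(net)


@pytest.fixture
def toy_negation():
    return parse_network("targets, factors\nA, !A")


@pytest.fixture
def toy_swap():
    return parse_network("targets, factors\nA, B\nB, A")


@pytest.fixture
def toy_rotor():
    # A <- !B, B <- A : a single 4-cycle through all states
    return parse_network("targets, factors\nA, !B\nB, A")
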