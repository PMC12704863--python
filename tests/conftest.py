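import pytest

from hormonet.network_io import load_hypertrophy_network


@pytest.fixture(scope="session")
def hypertrophy_model():
    return load_hypertrophy_network()


@pytest.fixture(scope="session")
def calibrated_model(hypertrophy_model):
    """Packaged network at its shipped (calibrated baseline) input weights."""
    return hypertrophy_model
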