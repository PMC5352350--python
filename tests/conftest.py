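import numpy as np
import pytest

from habm.datasets import bmsc_true_params, mic_true_params
from habm.networks import build_bmsc_network, build_mic_network, load_params


@pytest.fixture(scope="session")
def bmsc_net():
    return build_bmsc_network()


@pytest.fixture(scope="session")
def mic_net():
    return build_mic_network()


@pytest.fixture(scope="session")
def bmsc_payload():
    return load_params("bmsc")


@pytest.fixture(scope="session")
def mic_payload():
    return load_params("mic")


@pytest.fixture(scope="session")
def bmsc_truth():
    return bmsc_true_params()


@pytest.fixture(scope="session")
def mic_truth():
    return mic_true_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale lattice config for fast engine tests."""
    from habm.engine import SimulationConfig
    from habm.fields import Domain

    return SimulationConfig(
        domain=Domain(24, 24, 24), n_mic=30, n_mm=30, n_cd8=8, n_treg=2,
        horizon_h=96.0,
    )
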