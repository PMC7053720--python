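import numpy as np
import pytest

import levotap as lt


@pytest.fixture(scope="session")
def default_curve():
    """Calibrated steady-state D->frequency curve (cached package default)."""
    return lt.default_frequency_curve()


@pytest.fixture(scope="session")
def default_config():
    return lt.default_network_config()


@pytest.fixture(scope="session")
def moderate_synapses():
    """The shipped moderate-skill (100-epoch) synapse preset."""
    return lt.default_synapses(lt.default_network_config())


@pytest.fixture
def pk_typical():
    return lt.PKParameters(k12=1.2, k21=0.9, ketot=2.5)


@pytest.fixture
def pd_typical():
    return lt.PDParameters(ke3=0.02, T=15.0, D0=0.5, Dmax=1.2,
                           Dc50=0.6, ND=2.5)


@pytest.fixture
def clinical_times():
    return np.array([0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0,
                     120.0, 150.0, 180.0])
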