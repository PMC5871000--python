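import numpy as np
import pytest

from fln_kappa import IDFModel, default_config


@pytest.fixture
def idf():
    """Ambient-pressure IDF of the default fixture: N(17000, 60), nu0s = -600."""
    return IDFModel(center_nu00=17000.0, sigma0=60.0, nu_vac=17600.0)


@pytest.fixture
def clean_config():
    """Noiseless, background-free experiment at kappa = 0.25."""
    return default_config(kappa_true=0.25, noise_sd=0.0, background=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
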