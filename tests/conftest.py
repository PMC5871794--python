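import numpy as np
import pytest
from hypothesis import settings

from spectrokin import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_config():
    return synthetic.paper_scenario(seed=1)


@pytest.fixture(scope="session")
def noiseless_config():
    return synthetic.paper_scenario(seed=1, sigma_rel=0.0)


@pytest.fixture(scope="session")
def dielectric_spectra(paper_config):
    spectra, warns = synthetic.generate_dielectric_series(paper_config)
    return spectra, warns


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
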