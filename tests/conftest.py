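import numpy as np
import pytest

from cartkin.estimation import FitConfig, fit_product
from cartkin.model import AssayProtocol, REFERENCE_PARAMS
from cartkin import synthetic as syn


@pytest.fixture(scope="session")
def protocol():
    return AssayProtocol()


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def noisefree_config():
    return syn.CohortConfig(seed=42, noise_cv=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    return syn.CohortConfig(seed=42)


@pytest.fixture(scope="session")
def noisefree_product(noisefree_config):
    product = syn.draw_product(noisefree_config, 0)
    syn.emit_traces(product, noisefree_config)
    return product


@pytest.fixture(scope="session")
def noisy_product(noisy_config):
    product = syn.draw_product(noisy_config, 0)
    syn.emit_traces(product, noisy_config)
    return product


@pytest.fixture(scope="session")
def quick_fit_config():
    """Small multi-start budget for unit tests; the full budget is
    exercised in the acceptance suite."""
    return FitConfig(n_starts=15, seed=5, declared_addition_time=24.0)


@pytest.fixture(scope="session")
def noisefree_fit(noisefree_product, quick_fit_config):
    return fit_product(noisefree_product.dataset, quick_fit_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
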