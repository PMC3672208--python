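import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluxbma as fb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return fb.DesignConfig(seed=11)


@pytest.fixture(scope="session")
def layout(design):
    return fb.generate_layout(design)


@pytest.fixture(scope="session")
def exp_dataset(design):
    """One dataset simulated from the geostatistical structure."""
    ds, weights = fb.simulate_dataset(design, fb.GenerativeParams(structure="exp"))
    return ds, weights


@pytest.fixture(scope="session")
def fast_config():
    """Short chain for unit tests; long enough to stabilise the posterior."""
    return fb.McmcConfig(n_iter=4000, burn_in=1000, thin=3, seed=2)


@pytest.fixture(scope="session")
def exp_fit(exp_dataset, fast_config):
    ds, _ = exp_dataset
    return fb.fit_exp_geostat(ds, config=fast_config)


@pytest.fixture(scope="session")
def icar_fit(exp_dataset, fast_config):
    ds, weights = exp_dataset
    return fb.fit_icar(ds, weights, config=fast_config)


@pytest.fixture(scope="session")
def independent_fit(exp_dataset, fast_config):
    ds, _ = exp_dataset
    return fb.fit_independent(ds, config=fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
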