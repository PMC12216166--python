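import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import volabandit as vb

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def model_space():
    return vb.enumerate_model_space()


@pytest.fixture(scope="session")
def m11():
    return vb.get_spec("M11")


@pytest.fixture(scope="session")
def default_config():
    return vb.TaskConfig()


@pytest.fixture(scope="session")
def m11_params(m11):
    return vb.AgentParams.for_spec(
        m11, temperature=0.5, alpha_pos_stable=0.2, alpha_neg_stable=0.4,
        alpha_pos_volatile=0.6, alpha_neg_volatile=0.8)


@pytest.fixture(scope="session")
def small_cohort(m11, default_config):
    """A small reference-regime M11 cohort with its simulated trials."""
    hyper = vb.default_group_hyper(m11)
    cohort = vb.sample_cohort(hyper, 10, m11, seed=11)
    trials = vb.simulate_cohort(cohort, default_config, seed=11)
    return cohort, trials


@pytest.fixture(scope="session")
def m11_fit_small(m11, small_cohort):
    """A quick map_laplace fit of the small cohort, shared across tests."""
    _, trials = small_cohort
    settings_ = vb.FitSettings(algorithm="map_laplace", n_chains=2, n_samples=250, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vb.HierarchicalBanditModel(trials, m11).fit(settings_)
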