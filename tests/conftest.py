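import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from commocc.model import GroupData, PriorSpec
from commocc.synth import (default_design, moderate_truth, simulate_community,
                           simulate_landscape)


@pytest.fixture(scope="session")
def small_design():
    """4 routes x 6 sites x 5 points, 2 years, fully surveyed."""
    return default_design(n_routes=4, n_years=2)


@pytest.fixture(scope="session")
def small_bundle(small_design):
    site_cov, point_cov = simulate_landscape(small_design, seed=101)
    return simulate_community(small_design, site_cov, point_cov,
                              moderate_truth(), n_species=6, seed=102)


@pytest.fixture(scope="session")
def small_data(small_bundle):
    return GroupData.from_inputs(small_bundle.history, small_bundle.site_cov,
                                 small_bundle.point_cov)


@pytest.fixture(scope="session")
def prior():
    return PriorSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
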