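import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The default desk-scale study: 10 pairs, full planted structure."""
    from editscan.simulate import SimConfig, simulate

    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_sim):
    """Full pipeline output on the default study."""
    from editscan.workflow import run_pipeline

    return run_pipeline(default_sim, seed=1)


@pytest.fixture(scope="session")
def default_matrix(default_results):
    return default_results["matrix"]


@pytest.fixture(scope="session")
def truth_by_site(default_sim):
    from helpers import site_ids_of

    truth = default_sim.sites.copy()
    truth.index = site_ids_of(truth)
    return truth
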