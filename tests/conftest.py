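import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from pullpush import Parameters, resting_equilibrium, run_scenario_matrix


@pytest.fixture(scope="session")
def params():
    """The published parameter set."""
    return Parameters()


@pytest.fixture(scope="session")
def rest(params):
    return resting_equilibrium(params)


@pytest.fixture(scope="session")
def matrix(params):
    """All eleven scenarios, simulated once per session.

    Returns ``(records_by_scenario, trajectories_by_scenario)``.
    """
    records, trajs = run_scenario_matrix(params, return_trajectories=True)
    return {r.scenario: r for r in records}, trajs
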