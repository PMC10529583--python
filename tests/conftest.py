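import pytest
from hypothesis import HealthCheck, settings

from pacgate import presets, synthetic
from pacgate.states import (
    apply_constraints,
    build_transition_graph,
    enumerate_candidate_states,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def candidate_space():
    return enumerate_candidate_states()


@pytest.fixture(scope="session")
def achievable_space():
    return apply_constraints(enumerate_candidate_states())


@pytest.fixture(scope="session")
def gating_graph(achievable_space):
    return build_transition_graph(achievable_space)


@pytest.fixture(scope="session")
def wt_params():
    return presets.equilibrium_preset("wt")


@pytest.fixture(scope="session")
def calibrated_rates():
    """Wild-type rate set calibrated to the published wash-in/washout taus."""
    return synthetic.calibrated_rates()
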