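import pytest
from hypothesis import HealthCheck, settings

import flowmigrate as fm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default parameter set (40 segments, 8 cells each, 100/0 Pa)."""
    return fm.ModelParams()


@pytest.fixture(scope="session")
def a_branch(params):
    """Default A-branch network; treated as read-only by tests."""
    return fm.build_a_branch(params)


@pytest.fixture(scope="session")
def initial_flow(a_branch):
    """Flow solution for the untouched initial A-branch."""
    return fm.solve_flow(a_branch)
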