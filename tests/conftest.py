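import warnings

import numpy as np
import pytest

from rewardsurprise.behavior import AgentParams, simulate_behavior
from rewardsurprise.pipeline import CohortConfig, simulate_cohort
from rewardsurprise.schedules import ScheduleSpec, generate_session

warnings.filterwarnings("ignore", message="zero-variance predictor")


@pytest.fixture(scope="session")
def stable_session():
    """A 150-trial stable/unlearnable session with a fixed seed."""
    return generate_session(ScheduleSpec.for_type("stable"), 42)


@pytest.fixture(scope="session")
def small_session():
    """A 20-trial stable session for hand-checkable fixtures."""
    return generate_session(
        ScheduleSpec.for_type("stable", n_rewarded_trials=20), 7)


@pytest.fixture(scope="session")
def default_agent():
    return AgentParams()


@pytest.fixture(scope="session")
def stable_trials(stable_session, default_agent):
    return simulate_behavior(stable_session, default_agent, 3)


@pytest.fixture(scope="session")
def cohort_trials():
    """A 6-subject stable-only cohort's pooled attempt table."""
    cfg = CohortConfig(seed=11, session_counts={"stable": 6})
    _, trials = simulate_cohort(cfg)
    return trials


def perturbed_lapse_agent(**coef_overrides) -> AgentParams:
    coefs = AgentParams().lapse_coefs.copy()
    coefs.update(coef_overrides)
    return AgentParams(lapse_coefs=coefs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
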