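import numpy as np
import pandas as pd
import pytest

from structbandit import LearnerParams, task
from structbandit.learning import FitConfig


@pytest.fixture(scope="session")
def correct_agent_params():
    """A learner that knows the relational structure of each block type."""
    return {+1: LearnerParams(alpha=0.4, beta=5.0, h_ab=+1.0),
            -1: LearnerParams(alpha=0.4, beta=5.0, h_ab=-1.0)}


@pytest.fixture(scope="session")
def scanner_behavior(correct_agent_params):
    """One subject's scanner session with simulated choices."""
    specs, runs = task.scanner_session_specs(0)
    sched = task.generate_schedule(specs, seed=11, runs=runs)
    return task.simulate_agent(sched, correct_agent_params, seed=12)


@pytest.fixture(scope="session")
def full_behavior(correct_agent_params):
    """One subject's pre-scan + scanner behavior (all four block types twice)."""
    return task.simulate_subject(0, seed=21, params_by_structure=correct_agent_params)


@pytest.fixture(scope="session")
def fast_fit_config():
    return FitConfig(n_starts=4, seed=3)
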