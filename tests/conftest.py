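"""Shared fixtures: default and noise-free generator setups, small sessions."""

from dataclasses import replace

import pytest

from volstop.engine import TaskConfig, run_session
from volstop.synth import AgentParams, default_profiles, manipulation_mode


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def quiet_profiles():
    """Noise-free region profiles for exactness tests."""
    return {r: replace(p, noise_sd=0.0) for r, p in default_profiles().items()}


@pytest.fixture(scope="session")
def control():
    return manipulation_mode("control")


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def agent():
    return AgentParams()


@pytest.fixture(scope="session")
def traced_session(agent, profiles, control):
    """One traced 10-success session shared by read-only tests."""
    cfg = TaskConfig(n_success_target=10)
    return run_session(agent, profiles, cfg, control, seed=7,
                       synth_traces=True)


@pytest.fixture(scope="session")
def behavior_session(agent, profiles, control, task):
    """One full-size behavior-only session shared by read-only tests."""
    return run_session(agent, profiles, task, control, seed=42,
                       synth_traces=False)
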