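"""Shared fixtures: the default 2x2 design and a few pre-simulated subjects.

Subject simulation is the expensive step, so data-emulating subjects are
session-scoped and shared across test modules.
"""

import numpy as np
import pytest

import risksteer as rs


@pytest.fixture(scope="session")
def conditions():
    return rs.default_experiment()


@pytest.fixture(scope="session")
def obs_model():
    return rs.default_observation_model()


@pytest.fixture(scope="session")
def neutral_subject():
    """Risk-neutral subject with human-like execution noise, full design."""
    spec = rs.SubjectSpec(subject_id="s0", theta=0.0, motor_noise_cv=0.5)
    return rs.generate_subject(spec, seed=101)


@pytest.fixture(scope="session")
def averse_subject():
    """Clearly risk-averse subject with human-like execution noise."""
    spec = rs.SubjectSpec(subject_id="sA", theta=0.0012, motor_noise_cv=0.5)
    return rs.generate_subject(spec, seed=102)


@pytest.fixture(scope="session")
def ideal_subject():
    """Noise-free risk-neutral subject (no execution noise), full design."""
    spec = rs.SubjectSpec(subject_id="sI", theta=0.0)
    return rs.generate_subject(spec, seed=103)


@pytest.fixture(scope="session")
def scalar_toy():
    """Tiny scalar system for brute-force oracles."""
    dyn = rs.LinearDynamics(A=[[1.0]], B=[[1.0]], Omega=[[0.5]])
    cost = rs.CostSpec(Q_running=[[0.0]], Q_final=[[1.0]], R=[[0.3]])
    return dyn, cost
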