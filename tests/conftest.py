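"""Shared fixtures.

The expensive session-scoped fixture is one reference-configuration
community run (S=500, mu=0.5, sigma=0.3, lam=1e-8) recorded for 10,000
time units after a 2,000 time-unit transient; all headline-number tests
share it.  Smaller fixtures are generated per module.
"""

import pytest

import dlv


REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def reference_traj():
    """Desk-scale reference run: chaotic turnover of ~9 dominant species."""
    return dlv.reference_run(seed=REFERENCE_SEED, t_run=10_000.0)


@pytest.fixture(scope="session")
def reference_matrix(reference_traj):
    return reference_traj.interaction_matrix()


@pytest.fixture(scope="session")
def reference_summary(reference_traj, reference_matrix):
    return dlv.summarize(reference_traj, reference_matrix)


@pytest.fixture(scope="session")
def reference_dist(reference_traj):
    return dlv.afd_sad(reference_traj)


@pytest.fixture(scope="session")
def small_chaotic():
    """A fast chaotic community (S=100) for structural checks."""
    params = dlv.EcologicalParams(S=100, mu=0.5, sigma=0.3, lam=1e-8)
    M = dlv.sample_interactions(params, 3)
    settings = dlv.IntegrationSettings(t_burn=500.0, t_run=1000.0, seed_x0=4)
    traj = dlv.integrate(M, dlv.initial_condition(params, settings), settings)
    return traj, M
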