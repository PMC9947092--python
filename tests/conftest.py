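"""Shared fixtures: protocol, controller, and simulated cohorts.

The heavier cohorts are session-scoped so the recovery-style checks
(flux and clearance estimation across many virtual subjects) simulate
each subject once.
"""

from __future__ import annotations

import numpy as np
import pytest

import hypoclamp as hc
from hypoclamp.simulate import GroupTemplate, draw_subject_params


@pytest.fixture(scope="session")
def protocol():
    return hc.ProtocolConfig()


@pytest.fixture(scope="session")
def controller():
    return hc.ControllerConfig()


@pytest.fixture(scope="session")
def cn_subject_clean(protocol, controller):
    """Default non-surgical subject, full protocol, closed loop, no noise."""
    return hc.simulate_subject(protocol=protocol, controller=controller,
                               noise=False)


@pytest.fixture(scope="session")
def full_cohort(protocol, controller):
    """Default four-group cohort (8 per group) with measurement noise."""
    return hc.simulate_cohort(n_per_group=8, protocol=protocol,
                              controller=controller, seed=11, noise=True)


@pytest.fixture(scope="session")
def recovery_cohort(protocol, controller):
    """100 noisy virtual subjects spanning the parameter ranges of the
    default template, with their ground truths — the test bed for
    estimator-recovery properties."""
    template = GroupTemplate("CN")
    out = []
    for k in range(100):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=2024, spawn_key=(k,)))
        params = draw_subject_params(template, rng)
        rec, truth = hc.simulate_subject(
            params=params, protocol=protocol, controller=controller,
            seed=np.random.SeedSequence(entropy=2024, spawn_key=(k, 1)),
            subject_id=f"R{k:03d}", noise=True)
        out.append((rec, truth))
    return out


@pytest.fixture(scope="session")
def matched_steele():
    """Steele configuration matched to the simulator's perfectly mixed
    single pool (pool fraction 1, population volume)."""
    return hc.SteeleConfig(pool_fraction=1.0, v_steele=160.0)
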