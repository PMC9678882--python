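"""Shared fixtures: small planted cohorts and their fitted networks."""

from __future__ import annotations

import numpy as np
import pytest

from morbinet import (
    EstimationConfig,
    SimulationConfig,
    block_model,
    fit_mgm,
    sample_cohort,
)


@pytest.fixture(scope="session")
def small_planted():
    """3 blocks x 4 nodes, ring couplings; n=1500. Fast shared fixture."""
    model = block_model(n_blocks=3, block_size=4, theta_in=1.0, alpha=-1.0)
    cohort = sample_cohort(model, SimulationConfig(n=1500, seed=11))
    return model, cohort


@pytest.fixture(scope="session")
def small_network(small_planted):
    model, cohort = small_planted
    net = fit_mgm(cohort, EstimationConfig(gamma=0.25, seed=11))
    return model, cohort, net


@pytest.fixture(scope="session")
def strong_edge_fixture():
    """p=10 with one strong planted coupling theta_12 = 1.2; n=3000."""
    p = 10
    theta = np.zeros((p, p))
    theta[0, 1] = theta[1, 0] = 1.2
    model_blocks = np.zeros(p, dtype=int)
    from morbinet.synthetic import PlantedModel

    model = PlantedModel(theta, np.full(p, -1.0), model_blocks)
    cohort = sample_cohort(model, SimulationConfig(n=3000, seed=5))
    return model, cohort
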