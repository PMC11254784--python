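"""Shared fixtures: a small synthetic world and a reduced-MCMC fit.

The expensive fixtures are session-scoped so the recovery-style tests can
share one fitted posterior.
"""

from __future__ import annotations

import pytest

from inactivity import hier_model as hm
from inactivity.synthetic_world import (
    WorldConfig,
    default_survey_plan,
    simulate_survey_observations,
    simulate_world,
)


@pytest.fixture(scope="session")
def world():
    """3 regions x 6 countries, 2000-2022, default generative magnitudes."""
    return simulate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def observations(world):
    """Two surveys per country, n = 2000 per stratum, half the countries
    contributing one IPAQ-short survey (true offset +0.15 probit)."""
    specs = default_survey_plan(world, surveys_per_country=2, sample_size_per_stratum=2000)
    return [o for s in specs for o in simulate_survey_observations(world, s)]


@pytest.fixture(scope="session")
def fit_config():
    return hm.ModelConfig(n_draws=1000, chains=2, warmup=150, seed=7)


@pytest.fixture(scope="session")
def male_dataset(world, observations, fit_config):
    return hm.build_dataset(
        [o for o in observations if o.sex == "male"],
        world.covariate_frame(),
        world.region_of_country,
        fit_config,
    )


@pytest.fixture(scope="session")
def male_draws(male_dataset, fit_config):
    return hm.fit(male_dataset, fit_config)
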