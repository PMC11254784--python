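"""In-memory orchestration of the simulate -> fit -> aggregate -> assess chain.

These helpers glue the modules together without touching the filesystem;
the CSV/manifest pipeline in :mod:`inactivity.io_cli` is the persistent
counterpart.  They are what the analysis drivers, the recovery tests and
the acceptance script run.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import aggregation, hier_model, target_tracking
from .survey_processing import SEXES
from .synthetic_world import (
    TrueWorld,
    WorldConfig,
    default_survey_plan,
    population_frame,
    simulate_survey_observations,
    simulate_world,
)


def simulate_and_fit(
    world_cfg: WorldConfig,
    model_cfg: hier_model.ModelConfig,
    surveys_per_country: int = 2,
    sample_size_per_stratum: int = 2000,
    ipaq_share: float = 0.5,
) -> tuple[TrueWorld, list, dict[str, hier_model.PosteriorDraws]]:
    """Simulate a world and its surveys, then fit one model per sex."""
    world = simulate_world(world_cfg)
    specs = default_survey_plan(
        world,
        surveys_per_country=surveys_per_country,
        sample_size_per_stratum=sample_size_per_stratum,
        ipaq_share=ipaq_share,
    )
    observations = [o for s in specs for o in simulate_survey_observations(world, s)]
    draws_by_sex = {}
    for sex in SEXES:
        ds = hier_model.build_dataset(
            [o for o in observations if o.sex == sex],
            world.covariate_frame(),
            world.region_of_country,
            model_cfg,
        )
        draws_by_sex[sex] = hier_model.fit(ds, model_cfg)
    return world, observations, draws_by_sex


def predict_surfaces(
    world: TrueWorld,
    draws_by_sex: dict[str, hier_model.PosteriorDraws],
    pop: aggregation.PopulationTable,
    years: list[int] | None = None,
) -> dict[str, hier_model.PrevalenceSurface]:
    """Per-sex surfaces on the full world grid, plus the both-sex surface."""
    years = years or world.years
    covariates = world.covariate_frame()
    surfaces = {}
    for sex in SEXES:
        surfaces[sex] = hier_model.predict_surface(
            draws_by_sex[sex], world.countries, years, list(world.config.age_groups),
            covariates, region_of_country=world.region_of_country,
            augment_seed=world.config.seed,
        )
    surfaces["both"] = aggregation.combine_sexes(surfaces["male"], surfaces["female"], pop)
    return surfaces


def unit_coverage(world: TrueWorld, surface: hier_model.PrevalenceSurface, sex: str) -> float:
    """Fraction of country-year-age units whose truth lies in the 95% UI."""
    truth = world.prevalence_array(sex)
    lo = np.percentile(surface.values, 2.5, axis=0)
    hi = np.percentile(surface.values, 97.5, axis=0)
    return float(((truth >= lo) & (truth <= hi)).mean())


def assess_world(
    world: TrueWorld,
    draws_by_sex: dict[str, hier_model.PosteriorDraws],
    target_cfg: target_tracking.TargetConfig = target_tracking.TargetConfig(),
    final_year: int | None = None,
) -> dict[str, list[target_tracking.TargetAssessment]]:
    """Full target assessment per sex slice ('male', 'female', 'both').

    Groupings are the world itself, each region, and each country;
    age-standardised estimates drive the assessment.
    """
    final_year = final_year or world.config.year_range[1]
    years = list(range(target_cfg.baseline_year, final_year + 1))
    pop_years = years + [target_cfg.target_year]
    pop = aggregation.PopulationTable(population_frame(world, years=pop_years))
    surfaces = predict_surfaces(world, draws_by_sex, pop, years=years)
    std = aggregation.who_standard_population(list(world.config.age_groups))

    groups: dict[str, list[str]] = {"global": list(world.countries)}
    for c in world.countries:
        groups.setdefault(world.region_of_country[c], []).append(c)
    for c in world.countries:
        groups[c] = [c]

    projections = {}
    for sex in SEXES:
        draws = draws_by_sex[sex].augment(world.countries, world.region_of_country, world.config.seed)
        projections[sex] = target_tracking.project_surface(
            draws, surfaces[sex], target_cfg, from_year=final_year
        )
    projections["both"] = aggregation.combine_sexes(projections["male"], projections["female"], pop)

    out: dict[str, list[target_tracking.TargetAssessment]] = {}
    for sex in ("male", "female", "both"):
        stded = aggregation.age_standardised_prevalence(surfaces[sex], std, groups, pop)
        proj_est = aggregation.age_standardised_prevalence(projections[sex], std, groups, pop)
        by_key = {(e.grouping, e.year): e for e in stded}
        proj_by = {e.grouping: e for e in proj_est}
        out[sex] = [
            target_tracking.assess_target(
                by_key[(label, target_cfg.baseline_year)],
                by_key[(label, final_year)],
                proj_by[label],
                target_cfg,
            )
            for label in groups
        ]
    return out


def uniform_trend_config(slope: float, seed: int) -> WorldConfig:
    """A world whose every country shares exactly the given probit trend."""
    return dataclasses.replace(
        WorldConfig(seed=seed), global_slope=slope, sd_region_slope=0.0, sd_country_slope=0.0
    )


def country_on_track_share(
    assessments: dict[str, list[target_tracking.TargetAssessment]], world: TrueWorld
) -> float:
    """Share of countries classified on-track in the both-sex assessment."""
    per_country = [
        a for a in assessments["both"] if a.grouping in world.countries
    ]
    return float(np.mean([a.category.startswith("on_track") for a in per_country]))
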