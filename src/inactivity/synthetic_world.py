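"""Ground-truth worlds and simulated surveys with known structure.

The estimation pipeline is exercised end-to-end on synthetic data whose
generative process mirrors the analysis model: a probit-scale prevalence
surface with a region/country hierarchy on intercepts and linear time
trends, region-varying natural-cubic-spline age patterns, a country-year
covariate (an obesity-prevalence analogue), instrument-specific reporting
offsets, and survey noise beyond binomial sampling.  Because the truth is
known, parameter recovery, interval coverage and target classification can
all be tested without any real survey data.

Sexes are generated with independent hierarchy draws, matching the
analysis convention of fitting separate models per sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .splines import natural_cubic_basis
from .survey_processing import (
    INSTRUMENTS,
    SEXES,
    ActivityRecord,
    PrevalenceObservation,
)


class ConfigurationError(ValueError):
    """Raised for invalid world configurations."""


#: the seven reporting age bands (inclusive upper bounds; the top band is open)
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, math.inf),
)

#: age at which the open-ended top band is closed for midpoint purposes
OPEN_BAND_CLOSE_AGE = 97.0

#: probit of the 2010 global prevalence used as the default world-level anchor
GLOBAL_INTERCEPT_DEFAULT = float(stats.norm.ppf(0.264))


def band_midpoint(age_lo: float, age_hi: float) -> float:
    """Midpoint age of a band; an open-ended band is closed at 97 first."""
    hi = OPEN_BAND_CLOSE_AGE if math.isinf(age_hi) else age_hi
    return (age_lo + hi) / 2.0


def age_in_band(age: float, age_lo: float, age_hi: float) -> bool:
    """Band membership: bands have integer inclusive bounds, so [lo, hi + 1)."""
    if math.isinf(age_hi):
        return age >= age_lo
    return age_lo <= age < age_hi + 1.0


@dataclass
class WorldConfig:
    """Generative parameters of a synthetic world.

    All scale parameters are on the probit scale; slopes are per calendar
    year.  Defaults are anchored to the observed global picture: prevalence
    around 26% at the 2011 reference year rising by roughly 0.01 probit per
    year, with hierarchy spreads that make country prevalence span roughly
    3%-66%.
    """

    n_regions: int = 3
    countries_per_region: int = 6
    year_range: tuple[int, int] = (2000, 2022)
    reference_year: int = 2011
    age_groups: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    global_intercept: float = GLOBAL_INTERCEPT_DEFAULT
    global_slope: float = 0.01
    sd_region_intercept: float = 0.35
    sd_country_intercept: float = 0.25
    sd_region_slope: float = 0.008
    sd_country_slope: float = 0.006
    spline_coefficient_means: tuple[float, ...] = (0.3, 0.2, 0.4)
    sd_region_spline: float = 0.1
    spline_knots: tuple[float, ...] = (30.0, 60.0)
    spline_boundary: tuple[float, float] = (18.0, 85.0)
    instrument_biases: dict = field(
        default_factory=lambda: {"GPAQ": 0.0, "IPAQ_short": 0.15, "EB": -0.05, "other": 0.05}
    )
    covariate_effect: float = 0.2
    sd_covariate_country: float = 0.5
    covariate_trend: float = 0.02
    extra_sd_national: float = 0.05
    extra_sd_subnational: float = 0.10
    urban_offset: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ConfigurationError("region and country counts must be positive")
        for name in (
            "sd_region_intercept", "sd_country_intercept", "sd_region_slope",
            "sd_country_slope", "sd_region_spline", "sd_covariate_country",
            "extra_sd_national", "extra_sd_subnational",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.extra_sd_subnational < self.extra_sd_national:
            raise ConfigurationError("extra_sd_subnational must be >= extra_sd_national")
        if self.instrument_biases.get("GPAQ", None) != 0.0:
            raise ConfigurationError("reference instrument GPAQ must carry offset exactly 0")
        unknown = set(self.instrument_biases) - set(INSTRUMENTS)
        if unknown:
            raise ConfigurationError(f"unknown instruments in biases: {sorted(unknown)}")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError("year_range must be an ordered pair")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_range[0], self.year_range[1] + 1))


@dataclass(frozen=True)
class SurveySpec:
    """The design of one simulated survey."""

    country: str
    midyear: int
    sex_coverage: str = "both"  # both | male_only | female_only
    instrument: str = "GPAQ"
    representativeness: str = "national"  # national | subnational | urban_only
    sample_size_per_stratum: int = 1000
    age_bands_reported: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.sample_size_per_stratum < 1:
            raise ConfigurationError("sample_size_per_stratum must be >= 1")
        if self.sex_coverage not in ("both", "male_only", "female_only"):
            raise ConfigurationError(f"bad sex_coverage {self.sex_coverage!r}")
        if self.instrument not in INSTRUMENTS:
            raise ConfigurationError(f"bad instrument {self.instrument!r}")
        if self.representativeness not in ("national", "subnational", "urban_only"):
            raise ConfigurationError(f"bad representativeness {self.representativeness!r}")

    def sexes(self) -> tuple[str, ...]:
        if self.sex_coverage == "both":
            return SEXES
        return ("male",) if self.sex_coverage == "male_only" else ("female",)


@dataclass
class TrueWorld:
    """A fully known prevalence surface plus the parameters that built it."""

    config: WorldConfig
    regions: list[str]
    countries: list[str]
    region_of_country: dict[str, str]
    # probit surfaces: sex -> array (country, year, age_band)
    probit: dict[str, np.ndarray]
    covariate_by_country: dict[str, float]
    params: dict

    @property
    def years(self) -> list[int]:
        return self.config.years

    def covariate(self, country: str, year: int) -> float:
        return self.covariate_by_country[country] + self.config.covariate_trend * (
            year - self.config.reference_year
        )

    def _index(self, country: str, year: int, band: tuple[float, float]) -> tuple[int, int, int]:
        return (
            self.countries.index(country),
            self.years.index(year),
            list(self.config.age_groups).index(tuple(band)),
        )

    def true_probit(self, country: str, year: int, band: tuple[float, float], sex: str) -> float:
        c, y, a = self._index(country, year, band)
        return float(self.probit[sex][c, y, a])

    def true_prevalence(self, country: str, year: int, band: tuple[float, float], sex: str) -> float:
        return float(stats.norm.cdf(self.true_probit(country, year, band, sex)))

    def prevalence_array(self, sex: str) -> np.ndarray:
        return stats.norm.cdf(self.probit[sex])

    def covariate_frame(self) -> pd.DataFrame:
        rows = [
            {"country": c, "year": y, "covariate": self.covariate(c, y)}
            for c in self.countries
            for y in self.years
        ]
        return pd.DataFrame(rows)


def simulate_world(config: WorldConfig) -> TrueWorld:
    """Draw a ground-truth world from the generative model.

    The probit surface for each sex is

        global_intercept + u_region + u_country
        + (global_slope + g_region + g_country) * (year - reference_year)
        + spline(age_mid) . (theta_global + theta_region)
        + covariate_effect * covariate(country, year)

    with all hierarchy deviations drawn independently per sex.  Deterministic
    given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    regions = [f"R{i+1}" for i in range(cfg.n_regions)]
    countries = [f"R{i+1}C{j+1}" for i in range(cfg.n_regions) for j in range(cfg.countries_per_region)]
    region_idx = np.repeat(np.arange(cfg.n_regions), cfg.countries_per_region)
    region_of_country = {c: regions[region_idx[k]] for k, c in enumerate(countries)}

    years = np.array(cfg.years)
    t = years - cfg.reference_year
    mids = np.array([band_midpoint(lo, hi) for lo, hi in cfg.age_groups])
    B = natural_cubic_basis(mids, cfg.spline_knots, cfg.spline_boundary)  # (A, K)
    theta0 = np.asarray(cfg.spline_coefficient_means, dtype=float)
    if theta0.shape[0] != B.shape[1]:
        raise ConfigurationError(
            f"spline_coefficient_means has {theta0.shape[0]} entries; basis needs {B.shape[1]}"
        )

    cov_base = rng.normal(0.0, cfg.sd_covariate_country, size=len(countries))
    covariate_by_country = dict(zip(countries, cov_base))
    cov = cov_base[:, None] + cfg.covariate_trend * t[None, :]  # (C, Y)

    probit: dict[str, np.ndarray] = {}
    params: dict = {
        "regions": regions,
        "countries": countries,
        "region_of_country": region_of_country,
        "covariate_by_country": {c: float(v) for c, v in covariate_by_country.items()},
    }
    for sex in SEXES:
        u_r = rng.normal(0.0, cfg.sd_region_intercept, size=cfg.n_regions)
        u_c = rng.normal(0.0, cfg.sd_country_intercept, size=len(countries))
        g_r = rng.normal(0.0, cfg.sd_region_slope, size=cfg.n_regions)
        g_c = rng.normal(0.0, cfg.sd_country_slope, size=len(countries))
        th_r = rng.normal(0.0, cfg.sd_region_spline, size=(cfg.n_regions, theta0.shape[0]))

        intercept = cfg.global_intercept + u_r[region_idx] + u_c  # (C,)
        slope = cfg.global_slope + g_r[region_idx] + g_c  # (C,)
        age_term = (theta0[None, :] + th_r[region_idx]) @ B.T  # (C, A)
        surf = (
            intercept[:, None, None]
            + slope[:, None, None] * t[None, :, None]
            + age_term[:, None, :]
            + cfg.covariate_effect * cov[:, :, None]
        )
        probit[sex] = surf
        params[sex] = {
            "region_intercepts": u_r.tolist(),
            "country_intercepts": u_c.tolist(),
            "region_slopes": g_r.tolist(),
            "country_slopes": g_c.tolist(),
            "region_spline_deviations": th_r.tolist(),
            "country_total_slope": slope.tolist(),
        }
    return TrueWorld(
        config=cfg,
        regions=regions,
        countries=countries,
        region_of_country=region_of_country,
        probit=probit,
        covariate_by_country=covariate_by_country,
        params=params,
    )


def _survey_rng(world: TrueWorld, spec: SurveySpec, salt: int = 0) -> np.random.Generator:
    """Deterministic per-survey stream derived from the world seed and design."""
    return np.random.default_rng(
        [
            world.config.seed,
            world.countries.index(spec.country),
            spec.midyear,
            INSTRUMENTS.index(spec.instrument),
            ("national", "subnational", "urban_only").index(spec.representativeness),
            salt,
        ]
    )


def simulate_survey_observations(
    world: TrueWorld, spec: SurveySpec, rng: np.random.Generator | None = None
) -> list[PrevalenceObservation]:
    """Simulate one survey's reported prevalences by sex and age band.

    Each stratum's observed probit is the true probit plus the instrument
    offset, an urban-coverage offset when applicable, and design noise with
    a representativeness-specific SD; binomial sampling with the stratum n
    is layered on top.
    """
    cfg = world.config
    if spec.midyear not in world.years:
        raise ConfigurationError(f"midyear {spec.midyear} outside world year range {cfg.year_range}")
    if rng is None:
        rng = _survey_rng(world, spec)
    bands = spec.age_bands_reported or cfg.age_groups
    bias = cfg.instrument_biases.get(spec.instrument, 0.0)
    urban = spec.representativeness == "urban_only"
    extra_sd = cfg.extra_sd_national if spec.representativeness == "national" else cfg.extra_sd_subnational

    out = []
    for sex in spec.sexes():
        for lo, hi in bands:
            z = world.true_probit(spec.country, spec.midyear, (lo, hi), sex)
            z += bias + (cfg.urban_offset if urban else 0.0)
            z += rng.normal(0.0, extra_sd) if extra_sd > 0 else 0.0
            p = float(stats.norm.cdf(z))
            n = spec.sample_size_per_stratum
            k = int(rng.binomial(n, p))
            out.append(
                PrevalenceObservation(
                    country=spec.country,
                    year=spec.midyear,
                    sex=sex,
                    age_lo=lo,
                    age_hi=hi,
                    p_obs=k / n,
                    n_effective=float(n),
                    instrument=spec.instrument,
                    national=spec.representativeness == "national",
                    urban_only=urban,
                )
            )
    return out


def simulate_individual_records(
    world: TrueWorld,
    spec: SurveySpec,
    rng: np.random.Generator | None = None,
    target_fraction: float | None = None,
) -> list[ActivityRecord]:
    """Simulate GPAQ-style person-level records for one survey.

    Each respondent is insufficiently active with the stratum's biased true
    prevalence; weekly moderate-equivalent minutes are then drawn from a
    mixture (a point mass at zero plus log-normal components) placed on the
    correct side of the 150-minute rule, and split into GPAQ domains.  Every
    nonzero domain value is at least 10 minutes, so cleaning never flips a
    respondent across the sufficiency boundary.  ``target_fraction``
    overrides the world-derived prevalence (useful for calibration tests).
    """
    if spec.instrument != "GPAQ":
        raise ConfigurationError("individual records are generated for GPAQ surveys only")
    cfg = world.config
    if rng is None:
        rng = _survey_rng(world, spec, salt=1)
    bands = spec.age_bands_reported or cfg.age_groups
    urban = spec.representativeness == "urban_only"
    extra_sd = cfg.extra_sd_national if spec.representativeness == "national" else cfg.extra_sd_subnational

    records: list[ActivityRecord] = []
    pid = 0
    for sex in spec.sexes():
        for lo, hi in bands:
            if target_fraction is None:
                z = world.true_probit(spec.country, spec.midyear, (lo, hi), sex)
                z += cfg.urban_offset if urban else 0.0
                z += rng.normal(0.0, extra_sd) if extra_sd > 0 else 0.0
                q = float(stats.norm.cdf(z))
            else:
                q = float(target_fraction)
            hi_draw = OPEN_BAND_CLOSE_AGE if math.isinf(hi) else hi + 1.0
            n = spec.sample_size_per_stratum
            insufficient = rng.random(n) < q
            ages = rng.uniform(lo, hi_draw, size=n)
            weights = rng.uniform(0.8, 1.25, size=n)
            for i in range(n):
                pid += 1
                records.append(
                    _minutes_record(
                        rng,
                        person_id=f"{spec.country}-{spec.midyear}-{pid}",
                        age=float(ages[i]),
                        sex=sex,
                        insufficient=bool(insufficient[i]),
                        weight=float(weights[i]),
                    )
                )
    return records


def _minutes_record(
    rng: np.random.Generator,
    *,
    person_id: str,
    age: float,
    sex: str,
    insufficient: bool,
    weight: float,
) -> ActivityRecord:
    """Draw domain minutes on the requested side of the 150-minute rule."""
    if insufficient:
        if rng.random() < 0.35:
            total = 0.0  # point mass: fully inactive respondent
        else:
            total = float(np.exp(rng.normal(np.log(60.0), 0.8)))
            while total >= 149.0:
                total = float(np.exp(rng.normal(np.log(60.0), 0.8)))
    else:
        total = 150.0 + float(np.exp(rng.normal(np.log(120.0), 0.9)))
        total = min(total, 4000.0)  # stay well under the 16 h/day plausibility cap

    vig_equiv = total * float(rng.beta(1.0, 3.0))  # vigorous share of equivalent minutes
    vigorous = vig_equiv / 2.0
    moderate = total - 2.0 * vigorous
    # keep each nonzero component a >= 10-minute weekly total
    if 0 < vigorous < 10.0:
        moderate, vigorous = total, 0.0
    if 0 < moderate < 10.0:
        vigorous, moderate = total / 2.0, 0.0

    kw = dict.fromkeys(
        ("work_moderate", "work_vigorous", "travel", "leisure_moderate", "leisure_vigorous"), 0.0
    )
    if moderate > 0:
        kw[("work_moderate", "travel", "leisure_moderate")[rng.integers(3)]] = moderate
    if vigorous > 0:
        kw[("work_vigorous", "leisure_vigorous")[rng.integers(2)]] = vigorous
    return ActivityRecord(person_id=person_id, age=age, sex=sex, survey_weight=weight, **kw)


def population_frame(world: TrueWorld, years: Sequence[int] | None = None) -> pd.DataFrame:
    """Synthetic person counts by country, year, sex and age band.

    Country sizes are log-normal, age structure tapers with age, and totals
    grow slowly over time; deterministic given the world seed.
    """
    cfg = world.config
    rng = np.random.default_rng([cfg.seed, 10_007])
    years = list(years) if years is not None else world.years
    base = np.exp(rng.normal(np.log(5e6), 0.8, size=len(world.countries)))
    age_w = np.array([0.26, 0.19, 0.16, 0.14, 0.12, 0.08, 0.05])
    if len(cfg.age_groups) != len(age_w):
        w = np.linspace(1.5, 0.4, len(cfg.age_groups))
        age_w = w / w.sum()
    rows = []
    for k, c in enumerate(world.countries):
        for y in years:
            growth = 1.005 ** (y - cfg.year_range[0])
            for sex, share in (("male", 0.5), ("female", 0.5)):
                for (lo, hi), w in zip(cfg.age_groups, age_w):
                    rows.append(
                        {
                            "country": c,
                            "year": y,
                            "sex": sex,
                            "age_lo": lo,
                            "age_hi": hi,
                            "population": float(np.round(base[k] * growth * share * w)),
                        }
                    )
    return pd.DataFrame(rows)


def default_survey_plan(
    world: TrueWorld,
    surveys_per_country: int = 2,
    sample_size_per_stratum: int = 2000,
    ipaq_share: float = 0.5,
) -> list[SurveySpec]:
    """A simple survey plan: evenly spaced midyears per country, with a
    configurable share of countries contributing one IPAQ-short survey
    (their later one) and the rest GPAQ throughout."""
    y0, y1 = world.config.year_range
    midyears = np.linspace(y0 + 2, y1 - 2, surveys_per_country).round().astype(int)
    specs = []
    for k, c in enumerate(world.countries):
        ipaq_country = (k % max(1, round(1 / ipaq_share))) == 0 if ipaq_share > 0 else False
        for j, y in enumerate(midyears):
            instrument = "IPAQ_short" if (ipaq_country and j == len(midyears) - 1) else "GPAQ"
            specs.append(
                SurveySpec(
                    country=c,
                    midyear=int(y),
                    instrument=instrument,
                    sample_size_per_stratum=sample_size_per_stratum,
                )
            )
    return specs
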