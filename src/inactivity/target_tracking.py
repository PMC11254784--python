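"""Projection to 2030 and progress classification against the global target.

The WHA target is a 15% relative reduction in insufficient-activity
prevalence between 2010 and 2030.  Assuming the fitted linear 2010-22
trends continue, each unit's probit prevalence is extrapolated draw-wise
from the final estimation year to the target year using that draw's
country-level total slope; aggregation then uses target-year populations.
Progress combines a central on/off-track call (posterior means) with the
posterior probability of meeting the target:

    on track,  higher certainty  — central met,     pp >= 0.80
    on track,  lower certainty   — central met,     pp <  0.80
    off track, higher certainty  — central not met, pp <= 0.20
    off track, lower certainty   — central not met, pp >  0.20
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import AggregateEstimate, summarise
from .hier_model import PosteriorDraws, PrevalenceSurface
from .survey_processing import ValidationError

CATEGORIES = ("on_track_higher", "on_track_lower", "off_track_higher", "off_track_lower")


@dataclass(frozen=True)
class TargetConfig:
    baseline_year: int = 2010
    target_year: int = 2030
    relative_reduction: float = 0.15
    pp_high: float = 0.80
    pp_low: float = 0.20

    def __post_init__(self) -> None:
        if not self.baseline_year < self.target_year:
            raise ValidationError("baseline_year must precede target_year")
        if not 0.0 < self.relative_reduction < 1.0:
            raise ValidationError("relative_reduction must be in (0, 1)")
        if not self.pp_low < self.pp_high:
            raise ValidationError("pp_low must be < pp_high")


@dataclass
class TargetAssessment:
    grouping: str
    sex: str
    baseline_mean: float
    baseline_ui: tuple[float, float]
    projected_mean: float
    projected_ui: tuple[float, float]
    pp_meet: float
    central_met: bool
    category: str
    pp_increase: float
    pp_decrease: float

    def __post_init__(self) -> None:
        for v in (self.pp_meet, self.pp_increase, self.pp_decrease):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"posterior probability {v} outside [0, 1]")
        if self.pp_increase + self.pp_decrease > 1.0 + 1e-12:
            raise ValidationError("pp_increase + pp_decrease exceed 1")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


def project_surface(
    draws: PosteriorDraws,
    surface: PrevalenceSurface,
    cfg: TargetConfig = TargetConfig(),
    from_year: int | None = None,
) -> PrevalenceSurface:
    """Extrapolate a fitted surface to the target year, draw by draw.

    For every unit, probit(p_target) = probit(p_from) + (target_year -
    from_year) * (that draw's country-level total slope).  The covariate is
    implicitly held at its ``from_year`` value.  ``surface`` must have been
    predicted from (an augmentation of) ``draws`` so country axes align.
    """
    from_year = from_year if from_year is not None else max(surface.years)
    if from_year not in surface.years:
        raise ValidationError(f"surface does not contain from_year {from_year}")
    missing = [c for c in surface.countries if c not in draws.countries]
    if missing:
        raise ValidationError(
            f"countries {missing} not in draws; augment the draws before predicting"
        )
    horizon = cfg.target_year - from_year
    slopes = draws.total_country_slope()  # (N, C_draws)
    cols = [draws.countries.index(c) for c in surface.countries]
    z = stats.norm.ppf(surface.year_slice(from_year))  # (N, C, A)
    z = z + horizon * slopes[:, cols][:, :, None]
    return PrevalenceSurface(
        sex=surface.sex,
        countries=list(surface.countries),
        years=[cfg.target_year],
        age_groups=list(surface.age_groups),
        values=stats.norm.cdf(z)[:, :, None, :],
        metadata={**surface.metadata, "projected_from": from_year},
    )


def pp_meet_target(
    baseline_draws: np.ndarray, projected_draws: np.ndarray, cfg: TargetConfig = TargetConfig()
) -> float:
    """Fraction of paired draws with projected <= (1 - reduction) x baseline.

    Exactly reaching the reduced level counts as met.
    """
    b = np.asarray(baseline_draws, dtype=float)
    p = np.asarray(projected_draws, dtype=float)
    if b.shape != p.shape:
        raise ValidationError("baseline and projected draw vectors must have equal length")
    return float(np.mean(p <= (1.0 - cfg.relative_reduction) * b))


def classify_progress(central_met: bool, pp_meet: float, cfg: TargetConfig = TargetConfig()) -> str:
    """Four-way progress category from the central call and the posterior probability."""
    if not 0.0 <= pp_meet <= 1.0:
        raise ValidationError(f"pp_meet={pp_meet} outside [0, 1]")
    if central_met:
        return "on_track_higher" if pp_meet >= cfg.pp_high else "on_track_lower"
    return "off_track_higher" if pp_meet <= cfg.pp_low else "off_track_lower"


def pp_trend_direction(
    draws_baseline: np.ndarray, draws_final: np.ndarray
) -> tuple[float, float]:
    """Posterior probabilities that the trend is a true increase / decrease.

    Ties (exactly equal draws) count toward neither.
    """
    b = np.asarray(draws_baseline, dtype=float)
    f = np.asarray(draws_final, dtype=float)
    if b.shape != f.shape:
        raise ValidationError("draw vectors must have equal length")
    return float(np.mean(f > b)), float(np.mean(f < b))


def assess_target(
    baseline: AggregateEstimate,
    final: AggregateEstimate,
    projected: AggregateEstimate,
    cfg: TargetConfig = TargetConfig(),
) -> TargetAssessment:
    """Full assessment for one grouping: central call, pp, category, trend pps.

    The central on/off-track call compares posterior-mean projected
    prevalence with the posterior-mean baseline reduced by the target
    fraction.
    """
    if not (baseline.grouping == final.grouping == projected.grouping):
        raise ValidationError("estimates must refer to the same grouping")
    central_met = projected.mean <= (1.0 - cfg.relative_reduction) * baseline.mean
    pp = pp_meet_target(baseline.draws, projected.draws, cfg)
    pp_inc, pp_dec = pp_trend_direction(baseline.draws, final.draws)
    b_mean, b_lo, b_hi = summarise(baseline.draws)
    p_mean, p_lo, p_hi = summarise(projected.draws)
    return TargetAssessment(
        grouping=baseline.grouping,
        sex=baseline.sex,
        baseline_mean=b_mean,
        baseline_ui=(b_lo, b_hi),
        projected_mean=p_mean,
        projected_ui=(p_lo, p_hi),
        pp_meet=pp,
        central_met=bool(central_met),
        category=classify_progress(bool(central_met), pp, cfg),
        pp_increase=pp_inc,
        pp_decrease=pp_dec,
    )


def assessment_frame(assessments: Sequence[TargetAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "grouping": a.grouping,
                "sex": a.sex,
                "baseline_mean": a.baseline_mean,
                "baseline_ui_lo": a.baseline_ui[0],
                "baseline_ui_hi": a.baseline_ui[1],
                "projected_mean": a.projected_mean,
                "projected_ui_lo": a.projected_ui[0],
                "projected_ui_hi": a.projected_ui[1],
                "pp_meet": a.pp_meet,
                "central_met": a.central_met,
                "category": a.category,
                "pp_increase": a.pp_increase,
                "pp_decrease": a.pp_decrease,
            }
            for a in assessments
        ]
    )
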