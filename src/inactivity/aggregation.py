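"""Crude and age-standardised aggregation of posterior prevalence surfaces.

All aggregation is done draw-wise: each of the posterior draws of the
country x year x age surface is collapsed to the requested grouping
(country, region, income group, world) before summarising, so credible
intervals propagate exactly.  Age-standardisation weights age-group
prevalences by a fixed standard population *within* each country, then
population-weights the standardised country values (18+ totals) across the
group — matching how country-level age-standardised values are reported
alongside regional and global ones.  Uncertainty intervals are the 2.5th
and 97.5th percentiles of the draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hier_model import PrevalenceSurface
from .survey_processing import ValidationError

#: WHO world standard population (Ahmad et al. scale) aggregated to the
#: seven adult reporting bands; per-100k weights before normalisation.
_WHO_STANDARD_RAW = {
    (18, 29): 19538.0,  # 2/5 of 15-19 plus 20-24 and 25-29
    (30, 39): 14760.0,
    (40, 49): 12630.0,
    (50, 59): 9920.0,
    (60, 69): 6680.0,
    (70, 79): 3730.0,
    (80, float("inf")): 1545.0,
}


@dataclass
class StandardPopulation:
    """Fixed age weights for standardisation; weights sum to one."""

    age_groups: list[tuple[float, float]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.age_groups = [tuple(b) for b in self.age_groups]
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValidationError("standard population weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"standard population weights must sum to 1 (got {self.weights.sum()!r}); "
                "use StandardPopulation.normalised"
            )

    @classmethod
    def normalised(cls, age_groups: Sequence[tuple[float, float]], raw: Sequence[float]) -> "StandardPopulation":
        w = np.asarray(raw, dtype=float)
        return cls(list(age_groups), w / w.sum())

    def aligned(self, age_groups: Sequence[tuple[float, float]]) -> np.ndarray:
        """Weight vector ordered like ``age_groups``; errors on a mismatch."""
        try:
            return np.array([self.weights[self.age_groups.index(tuple(b))] for b in age_groups])
        except ValueError as e:
            raise ValidationError(f"standard population does not cover age groups {list(age_groups)}") from e


def who_standard_population(age_groups: Sequence[tuple[float, float]] | None = None) -> StandardPopulation:
    """The default WHO world standard collapsed to the adult reporting bands."""
    bands = [tuple(b) for b in (age_groups or _WHO_STANDARD_RAW)]
    return StandardPopulation.normalised(bands, [_WHO_STANDARD_RAW[b] for b in bands])


class PopulationTable:
    """Person counts by country x year x sex x age band."""

    def __init__(self, frame: pd.DataFrame):
        required = {"country", "year", "sex", "age_lo", "age_hi", "population"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"population table missing columns {sorted(missing)}")
        if (frame["population"] < 0).any():
            raise ValidationError("population counts must be >= 0")
        self.frame = frame.copy()
        self._lookup: dict[tuple, float] = {}
        for r in frame.itertuples():
            key = (str(r.country), int(r.year), str(r.sex), float(r.age_lo), float(r.age_hi))
            self._lookup[key] = self._lookup.get(key, 0.0) + float(r.population)

    def count(self, country: str, year: int, sex: str, band: tuple[float, float]) -> float:
        if sex == "both":
            return self.count(country, year, "male", band) + self.count(country, year, "female", band)
        key = (country, int(year), sex, float(band[0]), float(band[1]))
        if key not in self._lookup:
            raise ValidationError(f"missing population cell {key}")
        return self._lookup[key]

    def grid(
        self,
        countries: Sequence[str],
        years: Sequence[int],
        age_groups: Sequence[tuple[float, float]],
        sex: str,
    ) -> np.ndarray:
        """(C, Y, A) counts aligned to a surface grid; errors name the missing cell."""
        out = np.empty((len(countries), len(years), len(age_groups)))
        for ci, c in enumerate(countries):
            for yi, y in enumerate(years):
                for ai, b in enumerate(age_groups):
                    out[ci, yi, ai] = self.count(c, y, sex, tuple(b))
        return out


@dataclass
class AggregateEstimate:
    """A summarised group-year prevalence with its full draw vector."""

    grouping: str
    year: int
    sex: str
    mean: float
    ui_lo: float
    ui_hi: float
    draws: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.ui_lo <= self.ui_hi:
            raise ValidationError("ui_lo must be <= ui_hi")
        for v in (self.mean, self.ui_lo, self.ui_hi):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"estimate {v} outside [0, 1]")


def summarise(draws: np.ndarray) -> tuple[float, float, float]:
    """(posterior mean, 2.5th percentile, 97.5th percentile), linear interpolation."""
    d = np.asarray(draws, dtype=float)
    lo, hi = np.percentile(d, [2.5, 97.5])
    return float(d.mean()), float(lo), float(hi)


def _estimates(
    grouping_draws: Mapping[str, np.ndarray], years: Sequence[int], sex: str
) -> list[AggregateEstimate]:
    out = []
    for label, arr in grouping_draws.items():  # arr: (N, Y)
        for yi, year in enumerate(years):
            mean, lo, hi = summarise(arr[:, yi])
            out.append(AggregateEstimate(label, int(year), sex, mean, lo, hi, arr[:, yi]))
    return out


def crude_prevalence(
    surface: PrevalenceSurface,
    pop: PopulationTable,
    grouping: Mapping[str, Sequence[str]],
) -> list[AggregateEstimate]:
    """Population-weighted mean prevalence per group and year, draw-wise.

    ``grouping`` maps a label to the member countries, e.g.
    ``{"global": all_countries}`` or a region partition.
    """
    results: dict[str, np.ndarray] = {}
    for label, members in grouping.items():
        idx = [surface.countries.index(c) for c in members]
        P = pop.grid(members, surface.years, surface.age_groups, surface.sex)  # (C, Y, A)
        vals = surface.values[:, idx]  # (N, C, Y, A)
        num = np.einsum("ncya,cya->ny", vals, P)
        den = P.sum(axis=(0, 2))  # (Y,)
        results[label] = num / den[None, :]
    return _estimates(results, surface.years, surface.sex)


def age_standardised_prevalence(
    surface: PrevalenceSurface,
    std: StandardPopulation,
    grouping: Mapping[str, Sequence[str]],
    pop: PopulationTable,
) -> list[AggregateEstimate]:
    """Age-standardise within country, then population-weight across the group.

    Within each country the age-group prevalences are combined with the
    standard weights; across the group's countries the standardised values
    are weighted by 18+ population totals, per draw.
    """
    w = std.aligned(surface.age_groups)  # (A,)
    results: dict[str, np.ndarray] = {}
    for label, members in grouping.items():
        idx = [surface.countries.index(c) for c in members]
        P = pop.grid(members, surface.years, surface.age_groups, surface.sex)
        adult = P.sum(axis=2)  # (C, Y) 18+ totals
        std_c = np.einsum("ncya,a->ncy", surface.values[:, idx], w)  # (N, C, Y)
        results[label] = np.einsum("ncy,cy->ny", std_c, adult) / adult.sum(axis=0)[None, :]
    return _estimates(results, surface.years, surface.sex)


def combine_sexes(
    male: PrevalenceSurface, female: PrevalenceSurface, pop: PopulationTable
) -> PrevalenceSurface:
    """Both-sex surface: cell-wise population-weighted mean, draws paired by index."""
    if (
        male.countries != female.countries
        or male.years != female.years
        or male.age_groups != female.age_groups
        or male.n_draws != female.n_draws
    ):
        raise ValidationError("male and female surfaces must share grid and draw count")
    Pm = pop.grid(male.countries, male.years, male.age_groups, "male")
    Pf = pop.grid(male.countries, male.years, male.age_groups, "female")
    vals = (male.values * Pm[None] + female.values * Pf[None]) / (Pm + Pf)[None]
    return PrevalenceSurface(
        sex="both",
        countries=list(male.countries),
        years=list(male.years),
        age_groups=list(male.age_groups),
        values=vals,
        metadata={"combined_from": ("male", "female")},
    )


def estimates_frame(estimates: Sequence[AggregateEstimate]) -> pd.DataFrame:
    """Tidy CSV-ready table: grouping, year, sex, mean, ui_lo, ui_hi."""
    return pd.DataFrame(
        [
            {
                "grouping": e.grouping,
                "year": e.year,
                "sex": e.sex,
                "mean": e.mean,
                "ui_lo": e.ui_lo,
                "ui_hi": e.ui_hi,
            }
            for e in estimates
        ]
    )
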