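"""From questionnaire records to harmonised prevalence observations.

This module owns the survey side of the pipeline: the WHO sufficiency rule
(150 min/week of moderate activity, 75 of vigorous, or an equivalent
combination with vigorous minutes counting double), GPAQ-style cleaning,
survey-weighted prevalence by sex and age band with Kish effective sample
sizes, probit-scale crosswalk adjustments for non-comparable surveys
(urban-only coverage, IPAQ "low" category), and the eligibility screen
(year >= 2000, n >= 200, national or >= 3-area coverage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
INSTRUMENTS = ("GPAQ", "IPAQ_short", "EB", "other")

#: weekly minute threshold on moderate-equivalent activity
SUFFICIENT_EQUIVALENT_MINUTES = 150.0


class ValidationError(ValueError):
    """Raised when an input violates a contract (negative minutes, bad prevalence...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ActivityRecord:
    """One respondent's weekly activity minutes by domain and intensity.

    Travel activity carries moderate intensity only, following the GPAQ
    instrument design.
    """

    person_id: str
    age: float
    sex: str
    work_moderate: float = 0.0
    work_vigorous: float = 0.0
    travel: float = 0.0
    leisure_moderate: float = 0.0
    leisure_vigorous: float = 0.0
    survey_weight: float = 1.0
    psu: str | None = None
    stratum: str | None = None

    MINUTE_FIELDS = (
        "work_moderate",
        "work_vigorous",
        "travel",
        "leisure_moderate",
        "leisure_vigorous",
    )

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for f in self.MINUTE_FIELDS:
            v = getattr(self, f)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{f}={v!r} must be finite and >= 0")
        if not self.survey_weight >= 0:
            raise ValidationError(f"survey_weight must be >= 0, got {self.survey_weight}")


@dataclass
class PrevalenceObservation:
    """One survey x sex x age-band prevalence data point; the model's likelihood unit."""

    country: str
    year: int
    sex: str
    age_lo: float
    age_hi: float  # math.inf for an open-ended top band
    p_obs: float
    n_effective: float
    instrument: str
    national: bool = True
    urban_only: bool = False
    adjusted_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_obs <= 1.0:
            raise ValidationError(f"p_obs={self.p_obs} outside [0, 1]")
        if not self.n_effective > 0:
            raise ValidationError(f"n_effective={self.n_effective} must be > 0")
        if not self.age_lo < self.age_hi:
            raise ValidationError(f"need age_lo < age_hi, got [{self.age_lo}, {self.age_hi})")
        if self.year < 2000:
            raise ValidationError(f"year={self.year} before 2000")
        if self.instrument not in INSTRUMENTS:
            raise ValidationError(f"instrument must be one of {INSTRUMENTS}, got {self.instrument!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.adjusted_flags = frozenset(self.adjusted_flags)


@dataclass(frozen=True)
class Crosswalk:
    """Probit-affine map from a non-comparable prevalence to the national
    insufficient-activity scale: probit(p_adj) = intercept + slope * probit(p_obs).

    ``kind`` is either ``urban_to_national`` or ``ipaq_low_to_insufficient``.
    Coefficients are supplied via configuration (regression-derived in real
    analyses); the default identity crosswalk leaves data unchanged.
    """

    kind: str
    intercept: float = 0.0
    slope: float = 1.0
    residual_sd: float = 0.0

    KINDS = ("urban_to_national", "ipaq_low_to_insufficient")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"crosswalk kind must be one of {self.KINDS}")
        if not self.slope > 0:
            raise ValidationError(f"crosswalk slope must be > 0, got {self.slope}")

    def inverse(self) -> "Crosswalk":
        return Crosswalk(
            kind=self.kind,
            intercept=-self.intercept / self.slope,
            slope=1.0 / self.slope,
            residual_sd=self.residual_sd,
        )


@dataclass(frozen=True)
class CleaningRules:
    """Plausibility rules applied to GPAQ-style records before scoring.

    ``max_hours_per_day``: records whose summed weekly minutes exceed this
    many hours per day on average are rejected as implausible.
    ``min_bout_minutes``: weekly domain values below this are zeroed, since
    activity accumulates in bouts of at least 10 minutes.
    """

    max_hours_per_day: float = 16.0
    min_bout_minutes: float = 10.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def is_insufficiently_active(moderate_min_per_week: float, vigorous_min_per_week: float) -> bool:
    """True iff weekly activity falls short of the aerobic recommendation.

    Vigorous minutes count double, so the rule is
    ``moderate + 2 * vigorous < 150``.
    """
    for name, v in (("moderate", moderate_min_per_week), ("vigorous", vigorous_min_per_week)):
        if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
            raise ValidationError(f"{name} minutes must be finite and >= 0, got {v!r}")
    return moderate_min_per_week + 2.0 * vigorous_min_per_week < SUFFICIENT_EQUIVALENT_MINUTES


def clean_gpaq_record(
    record: ActivityRecord, rules: CleaningRules = CleaningRules()
) -> tuple[ActivityRecord | None, str | None]:
    """Apply plausibility rules; returns ``(record, None)`` or ``(None, reason)``.

    Rejection is a value, not an error: callers log the reason code.
    """
    total = sum(getattr(record, f) for f in ActivityRecord.MINUTE_FIELDS)
    if total > rules.max_hours_per_day * 60.0 * 7.0:
        return None, "implausible_total"
    changed = {
        f: 0.0
        for f in ActivityRecord.MINUTE_FIELDS
        if 0 < getattr(record, f) < rules.min_bout_minutes
    }
    return (replace(record, **changed) if changed else record), None


def weekly_minutes(record: ActivityRecord) -> tuple[float, float]:
    """Total weekly (moderate, vigorous) minutes across work, travel and leisure."""
    moderate = record.work_moderate + record.travel + record.leisure_moderate
    vigorous = record.work_vigorous + record.leisure_vigorous
    return moderate, vigorous


def kish_effective_n(weights: Sequence[float]) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_prevalence(
    records: Iterable[ActivityRecord],
    age_bands: Sequence[tuple[float, float]],
    *,
    country: str,
    year: int,
    instrument: str,
    national: bool = True,
    urban_only: bool = False,
    min_stratum_size: int = 25,
    rules: CleaningRules = CleaningRules(),
) -> list[PrevalenceObservation]:
    """Survey-weighted insufficient-activity prevalence by sex and age band.

    Records are cleaned, scored with the sufficiency rule, and pooled into
    the requested age bands.  Bands with fewer than ``min_stratum_size``
    respondents are merged upward into the next band (the final remnant
    merges downward); a stratum that still cannot reach the minimum is
    dropped with a logged warning.  ``n_effective`` is the Kish effective
    sample size of each emitted stratum.
    """
    records = list(records)
    if not records:
        raise ValidationError("weighted_prevalence requires at least one record")
    bands = [(float(lo), float(hi)) for lo, hi in age_bands]

    scored: dict[str, list[list[tuple[float, float]]]] = {s: [[] for _ in bands] for s in SEXES}
    for rec in records:
        cleaned, reason = clean_gpaq_record(rec, rules)
        if cleaned is None:
            logger.info("record %s rejected: %s", rec.person_id, reason)
            continue
        flag = float(is_insufficiently_active(*weekly_minutes(cleaned)))
        for i, (lo, hi) in enumerate(bands):
            # bands carry integer inclusive bounds: [lo, hi + 1), top band open
            if (math.isinf(hi) and cleaned.age >= lo) or lo <= cleaned.age < hi + 1.0:
                scored[cleaned.sex][i].append((flag, cleaned.survey_weight))
                break

    out: list[PrevalenceObservation] = []
    for sex in SEXES:
        emitted: list[tuple[float, float, list[tuple[float, float]]]] = []
        carry: list[tuple[float, float]] = []
        carry_lo: float | None = None
        for (lo, hi), rows in zip(bands, scored[sex]):
            pooled = carry + rows
            if not pooled:
                continue
            pooled_lo = carry_lo if carry_lo is not None else lo
            if len(pooled) < min_stratum_size:
                carry, carry_lo = pooled, pooled_lo
                continue
            emitted.append((pooled_lo, hi, pooled))
            carry, carry_lo = [], None
        if carry:
            if emitted:
                lo, hi, rows = emitted[-1]
                emitted[-1] = (lo, max(hi, bands[-1][1]), rows + carry)
            else:
                logger.warning(
                    "dropping %d %s records in %s/%d: below minimum stratum size %d",
                    len(carry), sex, country, year, min_stratum_size,
                )
        for lo, hi, rows in emitted:
            flags = np.array([f for f, _ in rows])
            w = np.array([wt for _, wt in rows])
            out.append(
                PrevalenceObservation(
                    country=country,
                    year=year,
                    sex=sex,
                    age_lo=lo,
                    age_hi=hi,
                    p_obs=float(np.average(flags, weights=w)),
                    n_effective=kish_effective_n(w),
                    instrument=instrument,
                    national=national,
                    urban_only=urban_only,
                )
            )
    return out


def apply_crosswalk(obs: PrevalenceObservation, cw: Crosswalk) -> PrevalenceObservation:
    """Map an observation onto the comparable national scale.

    probit(p_adj) = intercept + slope * probit(p_obs).  Boundary prevalences
    must be continuity-corrected upstream (see the model stage).
    """
    if not 0.0 < obs.p_obs < 1.0:
        raise ValidationError(
            f"crosswalk needs p_obs in (0, 1); apply a continuity correction first (got {obs.p_obs})"
        )
    z = stats.norm.ppf(obs.p_obs)
    p_adj = float(stats.norm.cdf(cw.intercept + cw.slope * z))
    return replace(
        obs,
        p_obs=p_adj,
        urban_only=False if cw.kind == "urban_to_national" else obs.urban_only,
        adjusted_flags=obs.adjusted_flags | {cw.kind},
    )


@dataclass(frozen=True)
class SurveyMetadata:
    """The eligibility-relevant facts about a survey."""

    survey_id: str
    year: int
    sample_size: int
    national: bool
    n_areas: int  # areas covered when not nationally representative
    all_domain_instrument: bool = True


def filter_eligibility(meta: SurveyMetadata) -> tuple[bool, list[str]]:
    """Screen a survey against the inclusion criteria.

    Returns ``(include, reasons)`` where ``reasons`` lists every failed
    criterion: ``sample_size`` (n < 200), ``pre_2000`` (fieldwork before
    2000), ``coverage`` (neither national nor >= 3 areas), ``domains``
    (instrument not covering work, travel and leisure).
    """
    reasons = []
    if meta.sample_size < 200:
        reasons.append("sample_size")
    if meta.year < 2000:
        reasons.append("pre_2000")
    if not meta.national and meta.n_areas < 3:
        reasons.append("coverage")
    if not meta.all_domain_instrument:
        reasons.append("domains")
    return (not reasons), reasons


def survey_midyear(start_year: int, end_year: int) -> int:
    """Midpoint of a multi-year fieldwork period, rounded down."""
    if end_year < start_year:
        raise ValidationError("end_year before start_year")
    return (start_year + end_year) // 2
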