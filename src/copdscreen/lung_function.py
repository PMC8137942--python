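"""Spirometric reference equations, GOLD severity thresholds, and FEV1
trajectories.

Predicted normal FEV1 (litres) for Chinese adults comes from sex-specific
log-linear reference equations in height and age plus an additive
age-spline term (``mspline``)::

    FEV1 = exp(b0 + b_h * ln(height_cm) + b_a * ln(age_years) + mspline)

The model evaluates the equation at a single cohort age, so only one spline
value per sex is identifiable; it is pinned down by calibrating 80% of
predicted FEV1 against the published mild-to-moderate GOLD boundary for
each sex (1.77 L female, 2.44 L male at the cohort's mean height and age).
Severity follows GOLD grading of percent-predicted FEV1: mild above 80%,
moderate 50-80%, severe/very severe below 50%.  Cohorts enter the model at
the midpoint of their grade (90%, 65%, 25% of predicted).

An :class:`Fev1Trajectory` is piecewise linear: treated (detected) patients
gain ``effect_per_month`` for ``effect_duration`` months, after which FEV1
declines linearly; untreated patients decline from the first month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "GOLD_MILD_MODERATE_FRACTION",
    "GOLD_MODERATE_SEVERE_FRACTION",
    "MIDPOINT_FRACTIONS",
    "PUBLISHED_MILD_MODERATE_THRESHOLD",
    "predicted_fev1",
    "calibrate_mspline",
    "default_mspline",
    "SeverityThresholds",
    "severity_thresholds",
    "Fev1Trajectory",
]

#: (intercept, ln-height coefficient, ln-age coefficient) per sex.
REFERENCE_COEFFICIENTS: Dict[str, tuple[float, float, float]] = {
    "male": (-10.61669, 2.27078, 0.06622),
    "female": (-9.69716, 2.09385, 0.02006),
}

GOLD_MILD_MODERATE_FRACTION = 0.80
GOLD_MODERATE_SEVERE_FRACTION = 0.50
MIDPOINT_FRACTIONS: Dict[str, float] = {"mild": 0.90, "moderate": 0.65, "severe": 0.25}

#: Published 80%-of-predicted boundaries (litres) used to calibrate the
#: spline term at the base cohort's height and age.
PUBLISHED_MILD_MODERATE_THRESHOLD: Dict[str, float] = {"female": 1.77, "male": 2.44}

_BASE_HEIGHT = {"female": 155.80, "male": 167.10}
_BASE_AGE = 59.59


def _check_sex(sex: str) -> None:
    if sex not in REFERENCE_COEFFICIENTS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def predicted_fev1(sex: str, height_cm: float, age_years: float, mspline: float = 0.0) -> float:
    """Predicted normal FEV1 in litres.

    Strictly increasing in height and in ``mspline``.  Raises
    :class:`ValueError` for non-positive height or age.
    """
    _check_sex(sex)
    if height_cm <= 0 or age_years <= 0:
        raise ValueError("height and age must be positive")
    b0, bh, ba = REFERENCE_COEFFICIENTS[sex]
    return math.exp(b0 + bh * math.log(height_cm) + ba * math.log(age_years) + mspline)


def calibrate_mspline(
    sex: str,
    anchor_fev1: float,
    anchor_fraction: float,
    height_cm: float,
    age_years: float,
) -> float:
    """Spline value making ``anchor_fraction * predicted`` equal ``anchor_fev1``.

    Closed form: ``m = ln(anchor / fraction) - (b0 + b_h ln h + b_a ln a)``.
    """
    _check_sex(sex)
    if anchor_fev1 <= 0 or anchor_fraction <= 0:
        raise ValueError("anchor FEV1 and fraction must be positive")
    if height_cm <= 0 or age_years <= 0:
        raise ValueError("height and age must be positive")
    b0, bh, ba = REFERENCE_COEFFICIENTS[sex]
    return math.log(anchor_fev1 / anchor_fraction) - (
        b0 + bh * math.log(height_cm) + ba * math.log(age_years)
    )


def default_mspline(sex: str) -> float:
    """Spline term calibrated against the published 80% boundary for ``sex``
    at the base cohort's mean height and age (about -0.162 for both sexes)."""
    return calibrate_mspline(
        sex,
        PUBLISHED_MILD_MODERATE_THRESHOLD[sex],
        GOLD_MILD_MODERATE_FRACTION,
        _BASE_HEIGHT[sex],
        _BASE_AGE,
    )


@dataclass(frozen=True)
class SeverityThresholds:
    """GOLD severity boundaries and state-entry midpoints, in litres."""

    sex: str
    predicted_fev1: float
    mild_moderate: float
    moderate_severe: float
    midpoints: Dict[str, float]


def severity_thresholds(sex: str, cohort, mspline: float | None = None) -> SeverityThresholds:
    """Severity boundaries for one sex of a cohort.

    ``cohort`` needs ``height_female`` / ``height_male`` and ``mean_age``
    attributes.  When ``mspline`` is omitted the calibrated default for the
    sex is used, so at the base cohort the boundaries reproduce the
    published 1.77/1.11 L (female) and 2.44/1.52 L (male) values.
    """
    _check_sex(sex)
    if mspline is None:
        mspline = default_mspline(sex)
    height = cohort.height_female if sex == "female" else cohort.height_male
    pred = predicted_fev1(sex, height, cohort.mean_age, mspline)
    return SeverityThresholds(
        sex=sex,
        predicted_fev1=pred,
        mild_moderate=GOLD_MILD_MODERATE_FRACTION * pred,
        moderate_severe=GOLD_MODERATE_SEVERE_FRACTION * pred,
        midpoints={k: f * pred for k, f in MIDPOINT_FRACTIONS.items()},
    )


@dataclass(frozen=True)
class Fev1Trajectory:
    """Piecewise-linear FEV1 path: gain for ``effect_duration`` months, then
    linear decline.  Undetected patients have ``effect_per_month = 0`` and
    ``effect_duration = 0`` so decline starts immediately."""

    initial_fev1: float
    decline_per_month: float
    effect_per_month: float = 0.0
    effect_duration: int = 0

    def fev1_at(self, t: float) -> float:
        """FEV1 in litres ``t`` months into the trajectory (floored at 0)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        value = (
            self.initial_fev1
            + self.effect_per_month * min(t, self.effect_duration)
            - self.decline_per_month * max(0.0, t - self.effect_duration)
        )
        return max(0.0, value)

    def time_to_threshold(self, threshold: float) -> float:
        """First integer cycle at which FEV1 is strictly below ``threshold``.

        Returns ``math.inf`` when the trajectory never crosses (no
        decline).  A trajectory already below the threshold returns 0.
        """
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.fev1_at(0) < threshold:
            return 0
        if self.decline_per_month <= 0:
            return math.inf
        peak = self.initial_fev1 + self.effect_per_month * self.effect_duration
        # crossing time of the declining segment (peak >= threshold here)
        t_star = self.effect_duration + (peak - threshold) / self.decline_per_month
        return int(math.floor(t_star)) + 1
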