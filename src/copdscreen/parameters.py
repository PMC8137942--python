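"""Model configuration: default inputs, file I/O, one-way perturbations, and
probabilistic draws.

The default :class:`ParameterSet` holds the complete base-case configuration
of the screening model: test accuracies, cohort composition, clinical event
probabilities, treatment effects on lung function, unit costs, health-state
utilities, and discount rates (2018 CNY throughout).  Every tunable value
carries one-way sensitivity bounds and a sampling distribution in
:data:`PARAMETER_SPECS`, which drives both :func:`owsa_variants` and
:func:`sample_parameter_set` — this module therefore doubles as the
synthetic-data generator for the analysis.

Distribution convention for probabilistic draws: the (low, high) bounds are
read as a central 95% interval around the base value, so sigma =
(high - low) / (2 * 1.96).  Probabilities, test accuracies, utilities and
utility corrections are drawn from method-of-moments beta distributions;
costs from gamma; treatment effects, the decline rate, heights and age from
normals truncated at zero; discount rates are held fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator
from scipy import stats

__all__ = [
    "SEVERITIES",
    "REGIMENS",
    "ParameterSpec",
    "PARAMETER_SPECS",
    "ScreeningTestParams",
    "ScreeningParams",
    "CohortProfile",
    "ClinicalParams",
    "CostUtilityParams",
    "Settings",
    "ParameterSet",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "owsa_variants",
    "sample_parameter_set",
    "parameter_schema",
    "update_parameters",
]

Severity = Literal["mild", "moderate", "severe"]
Regimen = Literal["lama_laba", "laba_ics", "laba", "lama", "triple"]

SEVERITIES: tuple[str, ...] = ("mild", "moderate", "severe")
REGIMENS: tuple[str, ...] = ("lama_laba", "laba_ics", "laba", "lama", "triple")

_SPLIT_TOL = 1e-9


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScreeningTestParams(_Base):
    """Accuracy and unit cost of one screening test."""

    sensitivity: float = Field(gt=0.0, le=1.0)
    specificity: float = Field(gt=0.0, le=1.0)
    unit_cost: float = Field(ge=0.0)
    requires_confirmation: bool = True


class ScreeningParams(_Base):
    portable: ScreeningTestParams
    questionnaire: ScreeningTestParams


class CohortProfile(_Base):
    """Composition of the screened chronic-bronchitis cohort."""

    n_patients: int = Field(default=1000, gt=0)
    copd_prevalence: float = Field(ge=0.0, le=1.0)
    severity_split: Dict[Severity, float]
    mean_age: float = Field(gt=0.0)
    pct_female_copd: float = Field(ge=0.0, le=1.0)
    pct_female_noncopd: float = Field(ge=0.0, le=1.0)
    height_female: float = Field(gt=0.0)
    height_male: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check_split(self) -> "CohortProfile":
        missing = set(SEVERITIES) - set(self.severity_split)
        if missing:
            raise ValueError(f"severity_split missing keys: {sorted(missing)}")
        total = sum(self.severity_split.values())
        if abs(total - 1.0) > _SPLIT_TOL:
            raise ValueError(f"severity_split sums to {total!r}, expected 1")
        if any(v < 0 for v in self.severity_split.values()):
            raise ValueError("severity_split fractions must be non-negative")
        return self


class ClinicalParams(_Base):
    """Disease-progression and event inputs.

    Probabilities labelled *annual* are converted to monthly cycle
    probabilities inside the engine; ``monthly_pneumonia_incidence`` is
    already per cycle.
    """

    fev1_decline_per_year: float = Field(ge=0.0)
    fev1_decline_overrides: Optional[Dict[Severity, float]] = None
    annual_detection_prob: Dict[Severity, float]
    treatment_effect_per_month: Dict[Regimen, float]
    treatment_effect_duration: int = Field(default=6, ge=0)
    annual_exacerbation_prob: Dict[Severity, float]
    pct_exacerbation_hospital: Dict[Severity, float]
    severe_exacerbation_mortality: float = Field(ge=0.0, le=1.0)
    monthly_pneumonia_incidence: float = Field(ge=0.0, le=1.0)
    pneumonia_mortality: float = Field(ge=0.0, le=1.0)
    background_mortality_annual: float = Field(default=0.0, ge=0.0, le=1.0)
    treatment_mix: Dict[Severity, Dict[Regimen, float]]

    @model_validator(mode="after")
    def _check(self) -> "ClinicalParams":
        for name, d in (
            ("annual_detection_prob", self.annual_detection_prob),
            ("annual_exacerbation_prob", self.annual_exacerbation_prob),
            ("pct_exacerbation_hospital", self.pct_exacerbation_hospital),
        ):
            missing = set(SEVERITIES) - set(d)
            if missing:
                raise ValueError(f"{name} missing keys: {sorted(missing)}")
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}]={v} outside [0, 1]")
        if set(self.treatment_mix) != set(SEVERITIES):
            raise ValueError("treatment_mix must have one entry per severity")
        for sev, mix in self.treatment_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > _SPLIT_TOL:
                raise ValueError(f"treatment_mix[{sev}] sums to {total!r}, expected 1")
            if any(w < 0 for w in mix.values()):
                raise ValueError(f"treatment_mix[{sev}] has negative weights")
        return self


class CostUtilityParams(_Base):
    """Unit costs (2018 CNY), utilities, and discounting."""

    drug_cost_per_month: Dict[Regimen, float]
    maintenance_cost_per_month: Dict[Severity, float]
    cb_treatment_cost_per_month: float = Field(ge=0.0)
    exacerbation_inpatient_cost: Dict[Severity, float]
    exacerbation_outpatient_cost: float = Field(ge=0.0)
    pneumonia_cost: float = Field(ge=0.0)
    confirmation_cost: float = Field(ge=0.0)
    state_utility: Dict[Severity, float]
    utility_correction_outpatient_exac: float = Field(ge=0.0, le=1.0)
    utility_correction_inpatient_exac: float = Field(ge=0.0, le=1.0)
    utility_correction_pneumonia: float = Field(ge=0.0, le=1.0)
    discount_rate_cost: float = Field(ge=0.0, le=0.10)
    discount_rate_effect: float = Field(ge=0.0, le=0.10)

    @model_validator(mode="after")
    def _check(self) -> "CostUtilityParams":
        for name, d in (
            ("drug_cost_per_month", self.drug_cost_per_month),
            ("maintenance_cost_per_month", self.maintenance_cost_per_month),
            ("exacerbation_inpatient_cost", self.exacerbation_inpatient_cost),
        ):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}]={v} is negative")
        missing = set(SEVERITIES) - set(self.state_utility)
        if missing:
            raise ValueError(f"state_utility missing keys: {sorted(missing)}")
        for k, v in self.state_utility.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"state_utility[{k}]={v} outside [0, 1]")
        return self


class Settings(_Base):
    """Run-level configuration (horizon, willingness to pay, display)."""

    wtp: float = Field(default=193932.0, gt=0.0)
    horizon_cycles: int = Field(default=480, ge=0)
    half_cycle_correction: bool = False
    usd_per_cny: float = Field(default=0.1511, gt=0.0)
    #: When true, patients detected late (after screening) also receive the
    #: 6-month FEV1 improvement window.  Default false: the improvement is
    #: modelled only for patients detected at screening entry, matching the
    #: two-trajectory (detected vs undetected) lung-function illustration;
    #: late-detected patients switch to COPD treatment without the FEV1 gain.
    late_detection_effect: bool = False


class ParameterSet(_Base):
    screening: ScreeningParams
    cohort: CohortProfile
    clinical: ClinicalParams
    cost_utility: CostUtilityParams
    settings: Settings = Field(default_factory=Settings)

    def content_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Per-parameter sensitivity bounds and sampling distributions
# ---------------------------------------------------------------------------

Distribution = Literal["beta", "gamma", "normal_trunc", "fixed"]
Group = Literal["probability", "cost", "utility", "effect", "anthropometric", "rate"]


@dataclass(frozen=True)
class ParameterSpec:
    """One tunable scalar: its base value, one-way bounds, and PSA law.

    ``path`` is the dotted location inside :class:`ParameterSet`, e.g.
    ``"screening.portable.sensitivity"``.
    """

    path: str
    base: float
    low: float
    high: float
    distribution: Distribution
    group: Group

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.path}: need low <= base <= high")
        if self.group in ("probability", "utility") and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            raise ValueError(f"{self.path}: {self.group} bounds outside [0, 1]")
        if self.group == "cost" and self.low < 0:
            raise ValueError(f"{self.path}: negative cost bound")

    @property
    def name(self) -> str:
        return self.path


def _spec(path, base, low, high, dist, group) -> ParameterSpec:
    return ParameterSpec(path, base, low, high, dist, group)


#: All tunable scalars with their one-way bounds.  Test accuracies and
#: heights vary by +-10%; hospital-treated exacerbation mortality spans
#: 0.5%-10%; chronic-bronchitis treatment cost spans 100-500 CNY; discount
#: rates span 0-5%; everything else varies by +-20% (probabilities capped
#: at 1).
PARAMETER_SPECS: tuple[ParameterSpec, ...] = (
    # screening tests
    _spec("screening.questionnaire.sensitivity", 0.8750, 0.7875, 0.9625, "beta", "probability"),
    _spec("screening.questionnaire.specificity", 0.3880, 0.3492, 0.4268, "beta", "probability"),
    _spec("screening.portable.sensitivity", 0.9990, 0.8991, 1.0000, "beta", "probability"),
    _spec("screening.portable.specificity", 0.9770, 0.8793, 1.0000, "beta", "probability"),
    # cohort composition
    _spec("cohort.copd_prevalence", 0.3137, 0.2510, 0.3764, "beta", "probability"),
    _spec("cohort.severity_split.mild", 0.3138, 0.2510, 0.3765, "beta", "probability"),
    _spec("cohort.severity_split.moderate", 0.4604, 0.3683, 0.5525, "beta", "probability"),
    _spec("cohort.severity_split.severe", 0.2258, 0.1806, 0.2710, "beta", "probability"),
    _spec("cohort.mean_age", 59.59, 47.67, 71.50, "normal_trunc", "anthropometric"),
    _spec("cohort.pct_female_copd", 0.2346, 0.1877, 0.2815, "beta", "probability"),
    _spec("cohort.pct_female_noncopd", 0.3539, 0.2831, 0.4247, "beta", "probability"),
    _spec("cohort.height_female", 155.80, 140.22, 171.38, "normal_trunc", "anthropometric"),
    _spec("cohort.height_male", 167.10, 150.39, 183.81, "normal_trunc", "anthropometric"),
    # clinical
    _spec("clinical.fev1_decline_per_year", 0.041, 0.033, 0.049, "normal_trunc", "rate"),
    _spec("clinical.annual_detection_prob.mild", 0.20, 0.16, 0.24, "beta", "probability"),
    _spec("clinical.annual_detection_prob.moderate", 0.50, 0.40, 0.60, "beta", "probability"),
    _spec("clinical.annual_detection_prob.severe", 0.90, 0.72, 1.00, "beta", "probability"),
    _spec("clinical.treatment_effect_per_month.lama_laba", 0.026, 0.021, 0.031, "normal_trunc", "effect"),
    _spec("clinical.treatment_effect_per_month.laba_ics", 0.031, 0.025, 0.037, "normal_trunc", "effect"),
    _spec("clinical.treatment_effect_per_month.laba", 0.013, 0.010, 0.016, "normal_trunc", "effect"),
    _spec("clinical.treatment_effect_per_month.lama", 0.022, 0.018, 0.027, "normal_trunc", "effect"),
    _spec("clinical.treatment_effect_per_month.triple", 0.025, 0.020, 0.030, "normal_trunc", "effect"),
    _spec("clinical.annual_exacerbation_prob.mild", 0.190, 0.152, 0.228, "beta", "probability"),
    _spec("clinical.annual_exacerbation_prob.moderate", 0.190, 0.152, 0.228, "beta", "probability"),
    _spec("clinical.annual_exacerbation_prob.severe", 0.265, 0.212, 0.318, "beta", "probability"),
    _spec("clinical.pct_exacerbation_hospital.mild", 0.6842, 0.5474, 0.8211, "beta", "probability"),
    _spec("clinical.pct_exacerbation_hospital.moderate", 0.6842, 0.5474, 0.8211, "beta", "probability"),
    _spec("clinical.pct_exacerbation_hospital.severe", 0.6604, 0.5283, 0.7925, "beta", "probability"),
    _spec("clinical.severe_exacerbation_mortality", 0.0128, 0.0050, 0.1000, "beta", "probability"),
    _spec("clinical.monthly_pneumonia_incidence", 0.0020, 0.0016, 0.0025, "beta", "probability"),
    _spec("clinical.pneumonia_mortality", 0.0333, 0.0266, 0.0399, "beta", "probability"),
    # costs
    _spec("cost_utility.drug_cost_per_month.lama_laba", 642.0, 513.0, 770.0, "gamma", "cost"),
    _spec("cost_utility.drug_cost_per_month.laba_ics", 114.0, 91.0, 136.0, "gamma", "cost"),
    _spec("cost_utility.drug_cost_per_month.laba", 124.0, 99.0, 149.0, "gamma", "cost"),
    _spec("cost_utility.drug_cost_per_month.lama", 253.0, 202.0, 303.0, "gamma", "cost"),
    _spec("cost_utility.drug_cost_per_month.triple", 366.0, 292.0, 439.0, "gamma", "cost"),
    _spec("cost_utility.maintenance_cost_per_month.mild", 23.0, 18.0, 27.0, "gamma", "cost"),
    _spec("cost_utility.maintenance_cost_per_month.moderate", 67.0, 54.0, 81.0, "gamma", "cost"),
    _spec("cost_utility.maintenance_cost_per_month.severe", 187.0, 150.0, 225.0, "gamma", "cost"),
    _spec("cost_utility.cb_treatment_cost_per_month", 288.0, 100.0, 500.0, "gamma", "cost"),
    _spec("cost_utility.exacerbation_inpatient_cost.mild", 8639.0, 6911.0, 10366.0, "gamma", "cost"),
    _spec("cost_utility.exacerbation_inpatient_cost.moderate", 17277.0, 13822.0, 20732.0, "gamma", "cost"),
    _spec("cost_utility.exacerbation_inpatient_cost.severe", 25915.0, 20732.0, 31099.0, "gamma", "cost"),
    _spec("cost_utility.exacerbation_outpatient_cost", 395.0, 316.0, 474.0, "gamma", "cost"),
    _spec("cost_utility.pneumonia_cost", 32394.0, 25916.0, 38873.0, "gamma", "cost"),
    _spec("screening.portable.unit_cost", 34.0, 27.0, 41.0, "gamma", "cost"),
    _spec("screening.questionnaire.unit_cost", 8.0, 6.0, 9.0, "gamma", "cost"),
    _spec("cost_utility.confirmation_cost", 220.0, 176.0, 264.0, "gamma", "cost"),
    # utilities
    _spec("cost_utility.state_utility.mild", 0.81, 0.65, 0.97, "beta", "utility"),
    _spec("cost_utility.state_utility.moderate", 0.72, 0.58, 0.86, "beta", "utility"),
    _spec("cost_utility.state_utility.severe", 0.67, 0.54, 0.80, "beta", "utility"),
    _spec("cost_utility.utility_correction_outpatient_exac", 0.85, 0.68, 0.99, "beta", "utility"),
    _spec("cost_utility.utility_correction_inpatient_exac", 0.50, 0.40, 0.60, "beta", "utility"),
    _spec("cost_utility.utility_correction_pneumonia", 0.50, 0.40, 0.60, "beta", "utility"),
    # discounting (varied one-way, held fixed in probabilistic draws)
    _spec("cost_utility.discount_rate_cost", 0.035, 0.0, 0.05, "fixed", "rate"),
    _spec("cost_utility.discount_rate_effect", 0.035, 0.0, 0.05, "fixed", "rate"),
)


def default_parameters() -> ParameterSet:
    """Base-case configuration of the screening model.

    Scalar values agree with :data:`PARAMETER_SPECS` entry-for-entry; the
    treatment mix encodes standard first-line prescribing by severity
    (mild: LAMA alone; moderate: half LAMA alone, half LABA+ICS;
    severe/very severe: equal thirds LABA+LAMA, LABA+ICS, and triple
    therapy).
    """
    third = 1.0 / 3.0
    return ParameterSet(
        screening=ScreeningParams(
            portable=ScreeningTestParams(
                sensitivity=0.999, specificity=0.977, unit_cost=34.0
            ),
            questionnaire=ScreeningTestParams(
                sensitivity=0.875, specificity=0.388, unit_cost=8.0
            ),
        ),
        cohort=CohortProfile(
            n_patients=1000,
            copd_prevalence=0.3137,
            severity_split={"mild": 0.3138, "moderate": 0.4604, "severe": 0.2258},
            mean_age=59.59,
            pct_female_copd=0.2346,
            pct_female_noncopd=0.3539,
            height_female=155.80,
            height_male=167.10,
        ),
        clinical=ClinicalParams(
            fev1_decline_per_year=0.041,
            annual_detection_prob={"mild": 0.20, "moderate": 0.50, "severe": 0.90},
            treatment_effect_per_month={
                "lama_laba": 0.026,
                "laba_ics": 0.031,
                "laba": 0.013,
                "lama": 0.022,
                "triple": 0.025,
            },
            treatment_effect_duration=6,
            annual_exacerbation_prob={"mild": 0.19, "moderate": 0.19, "severe": 0.265},
            pct_exacerbation_hospital={
                "mild": 0.6842,
                "moderate": 0.6842,
                "severe": 0.6604,
            },
            severe_exacerbation_mortality=0.0128,
            monthly_pneumonia_incidence=0.0020,
            pneumonia_mortality=0.0333,
            treatment_mix={
                "mild": {"lama": 1.0},
                "moderate": {"lama": 0.5, "laba_ics": 0.5},
                "severe": {"lama_laba": third, "laba_ics": third, "triple": third},
            },
        ),
        cost_utility=CostUtilityParams(
            drug_cost_per_month={
                "lama_laba": 642.0,
                "laba_ics": 114.0,
                "laba": 124.0,
                "lama": 253.0,
                "triple": 366.0,
            },
            maintenance_cost_per_month={"mild": 23.0, "moderate": 67.0, "severe": 187.0},
            cb_treatment_cost_per_month=288.0,
            exacerbation_inpatient_cost={
                "mild": 8639.0,
                "moderate": 17277.0,
                "severe": 25915.0,
            },
            exacerbation_outpatient_cost=395.0,
            pneumonia_cost=32394.0,
            confirmation_cost=220.0,
            state_utility={"mild": 0.81, "moderate": 0.72, "severe": 0.67},
            utility_correction_outpatient_exac=0.85,
            utility_correction_inpatient_exac=0.50,
            utility_correction_pneumonia=0.50,
            discount_rate_cost=0.035,
            discount_rate_effect=0.035,
        ),
        settings=Settings(),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON (by file extension)."""
    path = Path(path)
    data = params.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a parameter file (YAML or JSON).

    Raises :class:`pydantic.ValidationError` naming the offending field on
    schema or range violations.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return ParameterSet.model_validate(data)


def parameter_schema() -> dict:
    """JSON schema of the parameter file format."""
    return ParameterSet.model_json_schema()


# ---------------------------------------------------------------------------
# Path helpers
# ---------------------------------------------------------------------------


def get_value(params: ParameterSet, path: str) -> float:
    obj: object = params
    parts = path.split(".")
    for part in parts:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return float(obj)  # type: ignore[arg-type]


def _set_value(params: ParameterSet, path: str, value: float) -> None:
    obj: object = params
    parts = path.split(".")
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


def _renormalize_split(params: ParameterSet, fixed_key: str) -> None:
    """Rescale the other two severity fractions so the split sums to one.

    Perturbing or drawing one component of a composition breaks the
    sum-to-one constraint; the untouched components are scaled
    proportionally to absorb the change.
    """
    split = params.cohort.severity_split
    fixed = split[fixed_key]  # type: ignore[index]
    others = [k for k in SEVERITIES if k != fixed_key]
    rest = sum(split[k] for k in others)  # type: ignore[index]
    if rest <= 0:
        for k in others:
            split[k] = (1.0 - fixed) / len(others)  # type: ignore[index]
        return
    scale = (1.0 - fixed) / rest
    for k in others:
        split[k] *= scale  # type: ignore[index]


def _apply(params: ParameterSet, values: Dict[str, float]) -> ParameterSet:
    """Return a validated copy of ``params`` with ``values`` set by path."""
    out = params.model_copy(deep=True)
    split_keys = []
    for path, value in values.items():
        _set_value(out, path, value)
        if path.startswith("cohort.severity_split."):
            split_keys.append(path.rsplit(".", 1)[1])
    if len(split_keys) == 1:
        _renormalize_split(out, split_keys[0])
    elif len(split_keys) > 1:
        total = sum(out.cohort.severity_split.values())
        for k in SEVERITIES:
            out.cohort.severity_split[k] /= total  # type: ignore[index]
    return ParameterSet.model_validate(out.model_dump())


# ---------------------------------------------------------------------------
# One-way sensitivity variants
# ---------------------------------------------------------------------------


def update_parameters(params: ParameterSet, values: Dict[str, float]) -> ParameterSet:
    """Validated copy of ``params`` with dotted-path ``values`` applied
    (severity-split edits are renormalized to sum to one)."""
    return _apply(params, values)


def owsa_variants(
    params: ParameterSet | None = None,
) -> list[tuple[str, ParameterSet, ParameterSet]]:
    """One (name, low, high) parameter-set pair per tunable scalar.

    Only the named parameter differs from the base configuration, except
    that perturbing one severity-split fraction proportionally rescales the
    other two to preserve the sum-to-one constraint.  Probability and
    utility values are clipped to at most 1.
    """
    base = params if params is not None else default_parameters()
    out = []
    for spec in PARAMETER_SPECS:
        low = spec.low
        high = spec.high
        if spec.group in ("probability", "utility"):
            low, high = max(0.0, low), min(1.0, high)
        low_ps = _apply(base, {spec.path: low})
        high_ps = _apply(base, {spec.path: high})
        out.append((spec.path, low_ps, high_ps))
    return out


# ---------------------------------------------------------------------------
# Probabilistic draws
# ---------------------------------------------------------------------------


def _draw(spec: ParameterSpec, rng: np.random.Generator) -> float:
    sigma = (spec.high - spec.low) / (2.0 * 1.959963984540054)
    if spec.distribution == "fixed" or sigma == 0.0:
        return spec.base
    if spec.distribution == "beta":
        m = spec.base
        if m <= 0.0 or m >= 1.0:
            return m
        var = sigma * sigma
        vmax = m * (1.0 - m)
        if var >= vmax:
            # bounds too wide for a beta with this mean; fall back to the
            # uniform over the stated interval (clipped to [0, 1])
            return float(rng.uniform(max(0.0, spec.low), min(1.0, spec.high)))
        nu = vmax / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.distribution == "gamma":
        if spec.base <= 0.0:
            return spec.base
        shape = (spec.base / sigma) ** 2
        scale = sigma * sigma / spec.base
        return float(rng.gamma(shape, scale))
    if spec.distribution == "normal_trunc":
        a = (0.0 - spec.base) / sigma
        return float(
            stats.truncnorm.rvs(a, np.inf, loc=spec.base, scale=sigma, random_state=rng)
        )
    raise ValueError(f"unknown distribution {spec.distribution!r}")


def sample_parameter_set(params: ParameterSet | None = None, seed: int = 0) -> ParameterSet:
    """Draw one probabilistic parameter set.

    Deterministic given ``seed``; each drawn value lies in its group's
    support (probabilities and utilities in [0, 1], costs non-negative).
    ``fixed``-distribution parameters keep their base value.
    """
    base = params if params is not None else default_parameters()
    rng = np.random.default_rng(seed)
    values: Dict[str, float] = {}
    for spec in PARAMETER_SPECS:
        values[spec.path] = _draw(spec, rng)
    _enforce_utility_ordering(values, rng)
    return _apply(base, values)


_UTILITY_PATHS = tuple(f"cost_utility.state_utility.{s}" for s in SEVERITIES)


def _enforce_utility_ordering(values: Dict[str, float], rng: np.random.Generator) -> None:
    """Redraw the state-utility triple until mild >= moderate >= severe.

    Independent marginal draws would place the severe state above the
    moderate one in a sizeable share of samples — a logically incoherent
    health-state ordering that flips the direction of progression effects.
    Rejection sampling keeps the documented marginal distributions while
    restricting draws to the coherent region.
    """
    specs = [next(s for s in PARAMETER_SPECS if s.path == p) for p in _UTILITY_PATHS]
    triple = [values[p] for p in _UTILITY_PATHS]
    for _ in range(1000):
        if triple[0] >= triple[1] >= triple[2]:
            break
        triple = [_draw(s, rng) for s in specs]
    else:
        triple = sorted(triple, reverse=True)
    for path, v in zip(_UTILITY_PATHS, triple):
        values[path] = v
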