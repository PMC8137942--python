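"""One-time screening decision tree.

Each strategy arm screens the same cohort of chronic-bronchitis patients
once.  Test sensitivity and specificity split the cohort into expected
true/false positives and negatives; screen-positive patients undergo a
confirmatory spirometry test (assumed perfectly accurate), which rules out
the false positives.  True positives enter the Markov model *detected*,
false negatives *undetected*; without screening every COPD patient enters
undetected.  The tree uses expected-value cohort arithmetic — no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from . import lung_function as lf
from .parameters import CohortProfile, CostUtilityParams, ParameterSet, SEVERITIES
from .states import HealthState, SubCohort, make_state

__all__ = ["Arm", "TreeOutcome", "arms_from_parameters", "run_tree", "entry_states"]

ARM_NAMES = ("no_screening", "questionnaire", "portable_spirometer")


@dataclass(frozen=True)
class Arm:
    """One strategy arm: a screening test (or none) plus whether positives
    receive the confirmatory diagnostic test."""

    name: str
    test: Optional[object] = None  # ScreeningTestParams
    confirm_positives: bool = True

    def __post_init__(self) -> None:
        if self.name not in ARM_NAMES:
            raise ValueError(f"unknown arm {self.name!r}")
        if self.name == "no_screening" and self.test is not None:
            raise ValueError("no_screening arm cannot carry a test")
        if self.name != "no_screening" and self.test is None:
            raise ValueError(f"{self.name} arm requires a test")


def arms_from_parameters(
    params: ParameterSet, spirometer_confirmation: bool = True
) -> Dict[str, Arm]:
    """The three strategy arms of the base analysis."""
    return {
        "no_screening": Arm("no_screening"),
        "questionnaire": Arm("questionnaire", params.screening.questionnaire),
        "portable_spirometer": Arm(
            "portable_spirometer",
            params.screening.portable,
            confirm_positives=spirometer_confirmation,
        ),
    }


@dataclass(frozen=True)
class TreeOutcome:
    """Expected classification of the screened cohort.

    ``entry_distribution`` maps entry state names (``non_copd`` or
    ``det``/``undet`` x severity) to fractions per patient; counts are
    expected counts per ``n_patients``; ``upfront_cost`` is per cohort.
    """

    arm: str
    entry_distribution: Dict[str, float]
    true_positive: float
    false_positive: float
    true_negative: float
    false_negative: float
    upfront_cost: float
    n_patients: int

    @property
    def upfront_cost_per_patient(self) -> float:
        return self.upfront_cost / self.n_patients


def run_tree(
    arm: Arm, cohort: CohortProfile, cost_utility: CostUtilityParams
) -> TreeOutcome:
    """Classify the cohort through one arm's screening pathway.

    Screen-positive patients (true and false positives) each receive the
    confirmation test when the arm confirms positives; confirmation is
    assumed perfect, so false positives return to the non-COPD state.
    """
    n = cohort.n_patients
    prev = cohort.copd_prevalence
    if arm.test is None:
        sens, spec_ = 0.0, 1.0
        test_cost = 0.0
    else:
        sens, spec_ = arm.test.sensitivity, arm.test.specificity
        test_cost = arm.test.unit_cost

    tp = n * prev * sens
    fn = n * prev * (1.0 - sens)
    fp = n * (1.0 - prev) * (1.0 - spec_)
    tn = n * (1.0 - prev) * spec_

    dist: Dict[str, float] = {"non_copd": 1.0 - prev}
    for sev in SEVERITIES:
        frac_sev = prev * cohort.severity_split[sev]
        dist[f"det_{sev}"] = frac_sev * sens
        dist[f"undet_{sev}"] = frac_sev * (1.0 - sens)

    upfront = n * test_cost
    if arm.test is not None and arm.confirm_positives:
        upfront += (tp + fp) * cost_utility.confirmation_cost

    return TreeOutcome(
        arm=arm.name,
        entry_distribution=dist,
        true_positive=tp,
        false_positive=fp,
        true_negative=tn,
        false_negative=fn,
        upfront_cost=upfront,
        n_patients=n,
    )


def entry_states(outcome: TreeOutcome, params: ParameterSet) -> list[SubCohort]:
    """Initial sub-cohorts entering the Markov model.

    Stratified by sex, detection status, and severity; each sub-cohort's
    FEV1 clock starts at the midpoint of its severity grade.  Detected
    sub-cohorts carry the severity-specific mix-weighted treatment effect;
    undetected sub-cohorts decline from the first cycle.  The non-COPD
    fraction is carried as a single massless-in-outcomes sub-cohort so that
    total mass is conserved.
    """
    cohort = params.cohort
    clinical = params.clinical
    decline_m = clinical.fev1_decline_per_year / 12.0
    thresholds = {
        sex: lf.severity_thresholds(sex, cohort) for sex in ("female", "male")
    }
    effect_by_sev = {
        sev: sum(
            w * clinical.treatment_effect_per_month[reg]
            for reg, w in clinical.treatment_mix[sev].items()
        )
        for sev in SEVERITIES
    }
    subcohorts: list[SubCohort] = []
    sex_fracs_copd = {"female": cohort.pct_female_copd, "male": 1.0 - cohort.pct_female_copd}
    sex_fracs_non = {
        "female": cohort.pct_female_noncopd,
        "male": 1.0 - cohort.pct_female_noncopd,
    }
    for sex in ("female", "male"):
        # non-COPD patients: identical care in every arm, no further accrual
        subcohorts.append(
            SubCohort(
                state=HealthState.NON_COPD,
                sex=sex,
                fraction=outcome.entry_distribution["non_copd"] * sex_fracs_non[sex],
                trajectory=lf.Fev1Trajectory(
                    initial_fev1=thresholds[sex].predicted_fev1, decline_per_month=0.0
                ),
            )
        )
        for sev in SEVERITIES:
            midpoint = thresholds[sex].midpoints[sev]
            for detected in (True, False):
                key = ("det_" if detected else "undet_") + sev
                frac = outcome.entry_distribution[key] * sex_fracs_copd[sex]
                traj = lf.Fev1Trajectory(
                    initial_fev1=midpoint,
                    decline_per_month=decline_m,
                    effect_per_month=effect_by_sev[sev] if detected else 0.0,
                    effect_duration=clinical.treatment_effect_duration if detected else 0,
                )
                subcohorts.append(
                    SubCohort(
                        state=make_state(detected, sev),
                        sex=sex,
                        fraction=frac,
                        trajectory=traj,
                    )
                )
    return subcohorts
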