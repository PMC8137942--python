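"""Health states and sub-cohort bookkeeping shared by the decision tree and
the Markov engine."""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .lung_function import Fev1Trajectory

__all__ = ["HealthState", "SubCohort", "SEVERITY_INDEX", "SEX_INDEX"]

SEVERITY_INDEX = {"mild": 0, "moderate": 1, "severe": 2}
SEX_INDEX = {"female": 0, "male": 1}


class HealthState(str, enum.Enum):
    """The seven living model states plus absorbing death.

    Undetected COPD patients may stay, progress to the next severity,
    become detected, or die; detected patients may stay, progress, or die.
    Severity never regresses and detection never reverts.
    """

    NON_COPD = "non_copd"
    DET_MILD = "det_mild"
    DET_MODERATE = "det_moderate"
    DET_SEVERE = "det_severe"
    UNDET_MILD = "undet_mild"
    UNDET_MODERATE = "undet_moderate"
    UNDET_SEVERE = "undet_severe"
    DEATH = "death"

    @property
    def is_copd(self) -> bool:
        return self not in (HealthState.NON_COPD, HealthState.DEATH)

    @property
    def detected(self) -> bool:
        return self in (HealthState.DET_MILD, HealthState.DET_MODERATE, HealthState.DET_SEVERE)

    @property
    def severity(self) -> str | None:
        name = self.value
        for sev in ("mild", "moderate", "severe"):
            if name.endswith(sev):
                return sev
        return None


def make_state(detected: bool, severity: str) -> HealthState:
    return HealthState(("det_" if detected else "undet_") + severity)


@dataclass
class SubCohort:
    """A homogeneous slice of the cohort sharing one FEV1 trajectory.

    ``fraction`` is mass per screened patient; ``months_in_track`` is the
    FEV1 clock — cycles since this trajectory started (screening entry or
    late detection).
    """

    state: HealthState
    sex: str
    fraction: float
    trajectory: Fev1Trajectory
    months_in_track: int = 0

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fraction must be non-negative")
        if self.months_in_track < 0:
            raise ValueError("months_in_track must be non-negative")
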