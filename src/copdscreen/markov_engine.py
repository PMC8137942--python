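"""Monthly-cycle lifetime Markov cohort engine.

The cohort is carried as homogeneous sub-cohorts, each sharing one
deterministic FEV1 trajectory (tunnel semantics): severity is re-derived
every cycle from the trajectory's current FEV1 against the sex-specific
GOLD boundaries, so progression happens exactly in the cycle the path
crosses a boundary.  Severity never regresses below the grade a sub-cohort
held when its trajectory started, and detection never reverts.

Within each cycle the order of operations is fixed and documented:

1. events — monthly exacerbation probability (converted from annual) split
   into hospital-treated (with case fatality) versus community-treated;
   independent pneumonia incidence with its own case fatality; optional
   background mortality;
2. late detection — surviving undetected mass converts at the monthly
   detection probability of its current severity, pays the confirmatory
   test, and switches to COPD treatment; by default its FEV1 keeps
   declining (the improvement window belongs to patients detected at
   screening entry; see ``Settings.late_detection_effect``);
3. progression — implicit in the FEV1 relabelling above;
4. accrual — treatment/maintenance costs for detected mass,
   chronic-bronchitis treatment cost for undetected mass, expected event
   costs (fatal events still incur their cost), life-years and
   utility-weighted QALYs for survivors, with multiplicative utility
   corrections in event months;
5. discounting at monthly factors (1+r)^(-cycle/12).

Expected-value accrual is written so that the patient-level Monte-Carlo
simulation of the same rules (:func:`microsim_oracle`) has exactly the
cohort engine's result as its expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import lung_function as lf
from .economics import ArmResult, discount_factor
from .parameters import SEVERITIES, ParameterSet
from .screening_tree import Arm, TreeOutcome, entry_states, run_tree
from .states import SEVERITY_INDEX, SEX_INDEX, HealthState, SubCohort, make_state

__all__ = [
    "monthly_prob",
    "monthly_decline",
    "CycleLedger",
    "step_cycle",
    "run_arm",
    "microsim_oracle",
    "MicrosimResult",
]

_MASS_EPS = 1e-15  # sub-cohort masses below this are not split further

COST_COMPONENTS = (
    "drug",
    "maintenance",
    "cb_treatment",
    "exacerbation_inpatient",
    "exacerbation_outpatient",
    "pneumonia",
    "detection",
)


def monthly_prob(annual_p: float) -> float:
    """Convert an annual probability to a monthly cycle probability:
    ``1 - (1 - annual_p)**(1/12)``."""
    if not 0.0 <= annual_p <= 1.0:
        raise ValueError("annual probability must lie in [0, 1]")
    return 1.0 - (1.0 - annual_p) ** (1.0 / 12.0)


def monthly_decline(annual_decline: float) -> float:
    """Convert an FEV1 decline rate from L/year to L/month (divide by 12)."""
    if annual_decline < 0:
        raise ValueError("decline rate must be non-negative")
    return annual_decline / 12.0


@dataclass
class CycleLedger:
    """Per-cycle accounting: state occupancy, deaths by cause, cost
    components (undiscounted and discounted), life-years and QALYs."""

    cycle: int
    alive_by_state: Dict[str, float]
    deaths_exacerbation: float
    deaths_pneumonia: float
    deaths_background: float
    costs: Dict[str, float]
    costs_discounted: Dict[str, float]
    life_years: float
    qalys: float
    life_years_discounted: float
    qalys_discounted: float

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())

    @property
    def total_cost_discounted(self) -> float:
        return sum(self.costs_discounted.values())


class _Derived:
    """Per-parameter-set precomputation of severity-indexed arrays."""

    def __init__(self, params: ParameterSet):
        cl, cu, co = params.clinical, params.cost_utility, params.cohort
        overrides = cl.fev1_decline_overrides or {}
        self.decline_m = np.array(
            [
                monthly_decline(overrides.get(s, cl.fev1_decline_per_year))
                for s in SEVERITIES
            ]
        )
        thr = {sex: lf.severity_thresholds(sex, co) for sex in ("female", "male")}
        self.mm = np.array([thr["female"].mild_moderate, thr["male"].mild_moderate])
        self.ms = np.array([thr["female"].moderate_severe, thr["male"].moderate_severe])
        self.midpoints = np.array(
            [[thr[sex].midpoints[s] for s in SEVERITIES] for sex in ("female", "male")]
        )
        self.pe = np.array([monthly_prob(cl.annual_exacerbation_prob[s]) for s in SEVERITIES])
        self.hosp = np.array([cl.pct_exacerbation_hospital[s] for s in SEVERITIES])
        self.mort_ex = cl.severe_exacerbation_mortality
        self.p_pn = cl.monthly_pneumonia_incidence
        self.mort_pn = cl.pneumonia_mortality
        self.bg = monthly_prob(cl.background_mortality_annual)
        self.qdet = np.array([monthly_prob(cl.annual_detection_prob[s]) for s in SEVERITIES])
        self.effect_mix = np.array(
            [
                sum(w * cl.treatment_effect_per_month[r] for r, w in cl.treatment_mix[s].items())
                for s in SEVERITIES
            ]
        )
        self.effect_duration = cl.treatment_effect_duration
        self.drug = np.array(
            [
                sum(w * cu.drug_cost_per_month[r] for r, w in cl.treatment_mix[s].items())
                for s in SEVERITIES
            ]
        )
        self.maint = np.array([cu.maintenance_cost_per_month[s] for s in SEVERITIES])
        self.cb = cu.cb_treatment_cost_per_month
        self.inpat = np.array([cu.exacerbation_inpatient_cost[s] for s in SEVERITIES])
        self.outpat = cu.exacerbation_outpatient_cost
        self.pn_cost = cu.pneumonia_cost
        self.confirm = cu.confirmation_cost
        self.u = np.array([cu.state_utility[s] for s in SEVERITIES])
        c_out = cu.utility_correction_outpatient_exac
        c_in = cu.utility_correction_inpatient_exac
        c_pn = cu.utility_correction_pneumonia
        self.c_out, self.c_in, self.c_pn = c_out, c_in, c_pn
        # per-cycle composites (per unit mass at risk, by severity)
        self.d_ex = self.pe * self.hosp * self.mort_ex
        self.surv = (1.0 - self.d_ex) * (1.0 - self.p_pn * self.mort_pn) * (1.0 - self.bg)
        # E[utility correction x survival] factorises over independent events
        self.qe = (
            (1.0 - self.pe)
            + self.pe * (1.0 - self.hosp) * c_out
            + self.pe * self.hosp * (1.0 - self.mort_ex) * c_in
        )
        self.qp = (1.0 - self.p_pn) + self.p_pn * (1.0 - self.mort_pn) * c_pn
        self.rate_cost = cu.discount_rate_cost
        self.rate_effect = cu.discount_rate_effect
        self.half_cycle = params.settings.half_cycle_correction
        # FEV1 effect applied when an undetected patient is diagnosed late;
        # zero unless the optional late-detection-effect variant is enabled
        if params.settings.late_detection_effect:
            self.late_effect = self.effect_mix
            self.late_duration = self.effect_duration
        else:
            self.late_effect = np.zeros(len(SEVERITIES))
            self.late_duration = 0


class _EngineState:
    """Flat arrays of living COPD sub-cohorts (struct-of-arrays)."""

    __slots__ = (
        "frac", "sexi", "fev1", "init_fev1", "clock", "floor_sev", "sev",
        "effect", "dur", "is_det", "n", "cycle",
        "dead_exac", "dead_pneumonia", "dead_background", "non_copd",
    )

    def __init__(self, capacity: int):
        self.frac = np.zeros(capacity)
        self.sexi = np.zeros(capacity, dtype=np.int8)
        self.fev1 = np.zeros(capacity)
        self.init_fev1 = np.zeros(capacity)
        self.clock = np.zeros(capacity, dtype=np.int64)
        self.floor_sev = np.zeros(capacity, dtype=np.int8)
        self.sev = np.zeros(capacity, dtype=np.int8)
        self.effect = np.zeros(capacity)
        self.dur = np.zeros(capacity, dtype=np.int64)
        self.is_det = np.zeros(capacity, dtype=bool)
        self.n = 0
        self.cycle = 0
        self.dead_exac = 0.0
        self.dead_pneumonia = 0.0
        self.dead_background = 0.0
        self.non_copd = 0.0

    def _grow(self, extra: int) -> None:
        cap = len(self.frac)
        if self.n + extra <= cap:
            return
        new_cap = max(cap * 2, self.n + extra)
        for name in ("frac", "sexi", "fev1", "init_fev1", "clock",
                     "floor_sev", "sev", "effect", "dur", "is_det"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[: self.n] = arr[: self.n]
            setattr(self, name, grown)

    def add_row(
        self, frac, sexi, fev1, init_fev1, clock, floor_sev, effect, dur, is_det
    ) -> None:
        self._grow(1)
        i = self.n
        self.frac[i] = frac
        self.sexi[i] = sexi
        self.fev1[i] = fev1
        self.init_fev1[i] = init_fev1
        self.clock[i] = clock
        self.floor_sev[i] = floor_sev
        self.sev[i] = floor_sev
        self.effect[i] = effect
        self.dur[i] = dur
        self.is_det[i] = is_det
        self.n += 1

    def alive_mass(self) -> float:
        return float(self.frac[: self.n].sum())


def _state_from_subcohorts(subcohorts: Sequence[SubCohort], capacity: int) -> _EngineState:
    state = _EngineState(capacity)
    for sc in subcohorts:
        if sc.state is HealthState.NON_COPD:
            state.non_copd += sc.fraction
            continue
        if sc.state is HealthState.DEATH:
            continue
        traj = sc.trajectory
        state.add_row(
            frac=sc.fraction,
            sexi=SEX_INDEX[sc.sex],
            fev1=traj.fev1_at(sc.months_in_track),
            init_fev1=traj.initial_fev1,
            clock=sc.months_in_track,
            floor_sev=SEVERITY_INDEX[sc.state.severity],
            effect=traj.effect_per_month,
            dur=traj.effect_duration,
            is_det=sc.state.detected,
        )
    return state


def _subcohorts_from_state(state: _EngineState, decline_m: float) -> List[SubCohort]:
    out: List[SubCohort] = []
    sev_names = list(SEVERITIES)
    sex_names = ["female", "male"]
    if state.non_copd > 0.0:
        # the engine carries non-COPD mass as one scalar (sex is immaterial
        # to its zero accrual); re-emit it as a single sub-cohort
        out.append(
            SubCohort(
                state=HealthState.NON_COPD,
                sex="female",
                fraction=state.non_copd,
                trajectory=lf.Fev1Trajectory(initial_fev1=1.0, decline_per_month=0.0),
            )
        )
    for i in range(state.n):
        if state.frac[i] <= 0.0:
            continue
        traj = lf.Fev1Trajectory(
            initial_fev1=float(state.init_fev1[i]),
            decline_per_month=decline_m,
            effect_per_month=float(state.effect[i]),
            effect_duration=int(state.dur[i]),
        )
        out.append(
            SubCohort(
                state=make_state(bool(state.is_det[i]), sev_names[state.sev[i]]),
                sex=sex_names[state.sexi[i]],
                fraction=float(state.frac[i]),
                trajectory=traj,
                months_in_track=int(state.clock[i]),
            )
        )
    return out


def _step(state: _EngineState, der: _Derived, collect: bool) -> CycleLedger | None:
    """Advance the cohort one cycle in place; return the cycle ledger."""
    c = state.cycle + 1
    n = state.n
    sl = slice(0, n)
    frac = state.frac[sl]
    mass_in = float(frac.sum())

    # FEV1 clock and relabelling (progression)
    state.clock[sl] += 1
    in_window = state.clock[sl] <= state.dur[sl]
    prev_sev = state.sev[sl]
    delta = np.where(in_window, state.effect[sl], -der.decline_m[prev_sev])
    fev1 = state.fev1[sl]
    np.add(fev1, delta, out=fev1)
    np.maximum(fev1, 0.0, out=fev1)
    sexi = state.sexi[sl]
    label = (fev1 < der.mm[sexi]).astype(np.int8) + (fev1 < der.ms[sexi]).astype(np.int8)
    sev = np.maximum(label, state.floor_sev[sl])
    state.sev[sl] = sev

    # 1. events and deaths
    d_ex = der.d_ex[sev]
    deaths_ex = frac * d_ex
    survive_ex = frac - deaths_ex
    deaths_pn = survive_ex * (der.p_pn * der.mort_pn)
    survive_pn = survive_ex - deaths_pn
    deaths_bg = survive_pn * der.bg
    alive = survive_pn - deaths_bg
    if np.any(alive < -1e-12):
        raise RuntimeError("negative sub-cohort mass — internal inconsistency")

    pe = der.pe[sev]
    hosp = der.hosp[sev]
    cost_exac_in = float((frac * pe * hosp * der.inpat[sev]).sum())
    cost_exac_out = float((frac * pe * (1.0 - hosp)).sum()) * der.outpat
    cost_pn = float(frac.sum()) * der.p_pn * der.pn_cost

    # 2. late detection on survivors
    undet = ~state.is_det[sl]
    newdet = np.where(undet & (alive > _MASS_EPS), alive * der.qdet[sev], 0.0)

    # 4. accrual
    det_mask = state.is_det[sl]
    det_alive = np.where(det_mask, alive, 0.0)
    undet_alive = np.where(det_mask, 0.0, alive) - newdet
    drug_sev = der.drug[sev]
    maint_sev = der.maint[sev]
    cost_drug = float(((det_alive + newdet) * drug_sev).sum())
    cost_maint = float(((det_alive + newdet) * maint_sev).sum())
    cost_cb = float(undet_alive.sum()) * der.cb
    cost_detect = float(newdet.sum()) * der.confirm

    ly = float(alive.sum()) / 12.0
    qaly_weight = der.qe[sev] * der.qp * (1.0 - der.bg) * der.u[sev]
    qaly = float((frac * qaly_weight).sum()) / 12.0
    if der.half_cycle:
        # mid-cycle transition assumption: average start- and end-of-cycle mass
        ly = (mass_in / 12.0 + ly) / 2.0
        qaly = (float((frac * der.u[sev]).sum()) / 12.0 + qaly) / 2.0

    # apply survival and move newly detected mass to fresh trajectories
    state.frac[sl] = alive - newdet
    spawn_idx = np.nonzero(newdet > 0.0)[0]
    for i in spawn_idx:
        s = int(sev[i])
        state.add_row(
            frac=float(newdet[i]),
            sexi=int(sexi[i]),
            fev1=float(fev1[i]),
            init_fev1=float(fev1[i]),
            clock=0,
            floor_sev=s,
            effect=float(der.late_effect[s]),
            dur=der.late_duration,
            is_det=True,
        )

    de_x = float(deaths_ex.sum())
    de_p = float(deaths_pn.sum())
    de_b = float(deaths_bg.sum())
    state.dead_exac += de_x
    state.dead_pneumonia += de_p
    state.dead_background += de_b
    state.cycle = c

    mass_out = float(state.frac[: state.n].sum())
    if abs(mass_in - (mass_out + de_x + de_p + de_b)) > 1e-9:
        raise RuntimeError("cohort mass not conserved")

    dc = discount_factor(c, der.rate_cost)
    de = discount_factor(c, der.rate_effect)
    costs = {
        "drug": cost_drug,
        "maintenance": cost_maint,
        "cb_treatment": cost_cb,
        "exacerbation_inpatient": cost_exac_in,
        "exacerbation_outpatient": cost_exac_out,
        "pneumonia": cost_pn,
        "detection": cost_detect,
    }
    if not collect:
        return CycleLedger(
            cycle=c,
            alive_by_state={},
            deaths_exacerbation=de_x,
            deaths_pneumonia=de_p,
            deaths_background=de_b,
            costs=costs,
            costs_discounted={k: v * dc for k, v in costs.items()},
            life_years=ly,
            qalys=qaly,
            life_years_discounted=ly * de,
            qalys_discounted=qaly * de,
        )

    sl2 = slice(0, state.n)
    idx = state.sev[sl2] + 3 * state.is_det[sl2].astype(np.int8)
    occupancy = np.bincount(idx, weights=state.frac[sl2], minlength=6)
    alive_by_state = {
        "non_copd": state.non_copd,
        "undet_mild": float(occupancy[0]),
        "undet_moderate": float(occupancy[1]),
        "undet_severe": float(occupancy[2]),
        "det_mild": float(occupancy[3]),
        "det_moderate": float(occupancy[4]),
        "det_severe": float(occupancy[5]),
        "death": state.dead_exac + state.dead_pneumonia + state.dead_background,
    }
    return CycleLedger(
        cycle=c,
        alive_by_state=alive_by_state,
        deaths_exacerbation=de_x,
        deaths_pneumonia=de_p,
        deaths_background=de_b,
        costs=costs,
        costs_discounted={k: v * dc for k, v in costs.items()},
        life_years=ly,
        qalys=qaly,
        life_years_discounted=ly * de,
        qalys_discounted=qaly * de,
    )


def step_cycle(
    subcohorts: Sequence[SubCohort], params: ParameterSet, cycle: int
) -> tuple[List[SubCohort], CycleLedger]:
    """Advance a sub-cohort list one cycle.

    Functional wrapper around the array engine for inspection and testing;
    ``cycle`` is the index of the cycle being executed (1-based), used for
    discounting.
    """
    der = _Derived(params)
    n_undet = sum(
        1 for sc in subcohorts if sc.state.is_copd and not sc.state.detected
    )
    state = _state_from_subcohorts(subcohorts, capacity=len(subcohorts) + n_undet + 1)
    state.cycle = cycle - 1
    ledger = _step(state, der, collect=True)
    assert ledger is not None
    decline_uniform = float(der.decline_m[0])
    return _subcohorts_from_state(state, decline_uniform), ledger


def run_arm(
    arm: Arm,
    params: ParameterSet,
    horizon: Optional[int] = None,
    collect_ledger: bool = False,
) -> ArmResult:
    """Run the decision tree and the full Markov horizon for one arm.

    Returns discounted per-screened-patient totals; cycles stop at the
    horizon (default from settings, 480 months) or when living COPD mass
    falls below 1e-9.
    """
    if horizon is None:
        horizon = params.settings.horizon_cycles
    outcome = run_tree(arm, params.cohort, params.cost_utility)
    subcohorts = entry_states(outcome, params)
    der = _Derived(params)
    n_rows = sum(1 for sc in subcohorts if sc.state.is_copd)
    state = _state_from_subcohorts(subcohorts, capacity=n_rows + 6 * (horizon + 2))

    upfront = outcome.upfront_cost_per_patient
    cost_disc = {k: 0.0 for k in COST_COMPONENTS}
    cost_undisc = {k: 0.0 for k in COST_COMPONENTS}
    ly_d = qaly_d = ly_u = qaly_u = 0.0
    ledgers: List[CycleLedger] = []
    for _ in range(horizon):
        if state.alive_mass() < 1e-9:
            break
        ledger = _step(state, der, collect=collect_ledger)
        assert ledger is not None
        for k in COST_COMPONENTS:
            cost_disc[k] += ledger.costs_discounted[k]
            cost_undisc[k] += ledger.costs[k]
        ly_d += ledger.life_years_discounted
        qaly_d += ledger.qalys_discounted
        ly_u += ledger.life_years
        qaly_u += ledger.qalys
        if collect_ledger:
            ledgers.append(ledger)

    components = dict(cost_disc)
    components["upfront"] = upfront
    total_cost = upfront + sum(cost_disc.values())
    ledger_df = None
    if collect_ledger:
        rows = []
        for lg in ledgers:
            row = {"cycle": lg.cycle}
            row.update({f"alive_{k}": v for k, v in lg.alive_by_state.items()})
            row.update(
                deaths_exacerbation=lg.deaths_exacerbation,
                deaths_pneumonia=lg.deaths_pneumonia,
                deaths_background=lg.deaths_background,
                life_years=lg.life_years,
                qalys=lg.qalys,
                life_years_discounted=lg.life_years_discounted,
                qalys_discounted=lg.qalys_discounted,
            )
            row.update({f"cost_{k}": v for k, v in lg.costs.items()})
            row.update({f"cost_disc_{k}": v for k, v in lg.costs_discounted.items()})
            rows.append(row)
        ledger_df = pd.DataFrame(rows)

    return ArmResult(
        arm=arm.name,
        total_cost=total_cost,
        life_years=ly_d,
        qalys=qaly_d,
        cost_components=components,
        upfront_cost=upfront,
        undiscounted={
            "total_cost": upfront + sum(cost_undisc.values()),
            "life_years": ly_u,
            "qalys": qaly_u,
            **{f"cost_{k}": v for k, v in cost_undisc.items()},
        },
        ledger=ledger_df,
    )


@dataclass
class MicrosimResult:
    """Patient-level simulation output with per-patient accruals for
    standard-error computation."""

    result: ArmResult
    per_patient_cost: np.ndarray
    per_patient_qaly: np.ndarray
    per_patient_ly: np.ndarray

    def standard_error(self, which: str = "cost") -> float:
        arr = {
            "cost": self.per_patient_cost,
            "qaly": self.per_patient_qaly,
            "ly": self.per_patient_ly,
        }[which]
        return float(arr.std(ddof=1) / math.sqrt(len(arr)))


def microsim_oracle(
    arm: Arm,
    params: ParameterSet,
    n_patients: int = 5000,
    seed: int = 0,
    horizon: Optional[int] = None,
) -> MicrosimResult:
    """Individual-level Monte-Carlo simulation of the same model rules.

    Every rule (event ordering, costs, corrections, trajectories) mirrors
    the cohort engine, so the expectation of the per-patient accruals
    equals the cohort result; the treatment mix is applied as a blended
    regimen, exactly as in the cohort engine.  Deterministic given
    ``seed``.
    """
    if horizon is None:
        horizon = params.settings.horizon_cycles
    rng = np.random.default_rng(seed)
    der = _Derived(params)
    co = params.cohort
    n = n_patients

    copd = rng.random(n) < co.copd_prevalence
    split = np.array([co.severity_split[s] for s in SEVERITIES])
    sev0 = np.searchsorted(np.cumsum(split), rng.random(n), side="right").astype(np.int8)
    sev0 = np.minimum(sev0, 2)
    p_female = np.where(copd, co.pct_female_copd, co.pct_female_noncopd)
    sexi = (rng.random(n) >= p_female).astype(np.int8)  # 0=female, 1=male

    if arm.test is not None:
        positive = np.where(
            copd,
            rng.random(n) < arm.test.sensitivity,
            rng.random(n) < (1.0 - arm.test.specificity),
        )
        upfront = np.full(n, arm.test.unit_cost)
        if arm.confirm_positives:
            upfront += positive * params.cost_utility.confirmation_cost
    else:
        positive = np.zeros(n, dtype=bool)
        upfront = np.zeros(n)

    detected = copd & positive
    alive = copd.copy()
    fev1 = der.midpoints[sexi, sev0]
    clock = np.zeros(n, dtype=np.int64)
    floor_sev = sev0.copy()
    sev = sev0.copy()
    eff = np.where(detected, der.effect_mix[sev0], 0.0)
    dur = np.where(detected, der.effect_duration, 0)
    is_det = detected.copy()

    cost = upfront.copy()
    qaly = np.zeros(n)
    ly = np.zeros(n)

    for c in range(1, horizon + 1):
        if not alive.any():
            break
        m = alive
        clock[m] += 1
        in_win = clock <= dur
        fev1[m] += np.where(in_win[m], eff[m], -der.decline_m[sev[m]])
        np.maximum(fev1, 0.0, out=fev1)
        label = (fev1 < der.mm[sexi]).astype(np.int8) + (fev1 < der.ms[sexi]).astype(np.int8)
        sev = np.where(m, np.maximum(label, floor_sev), sev).astype(np.int8)

        u_ex = rng.random(n)
        u_h = rng.random(n)
        u_dx = rng.random(n)
        u_pn = rng.random(n)
        u_dp = rng.random(n)
        u_bg = rng.random(n)
        u_det = rng.random(n)

        exac = m & (u_ex < der.pe[sev])
        hosp_ev = exac & (u_h < der.hosp[sev])
        out_ev = exac & ~hosp_ev
        die_ex = hosp_ev & (u_dx < der.mort_ex)
        pn_ev = m & (u_pn < der.p_pn)
        die_pn_draw = pn_ev & (u_dp < der.mort_pn)
        die_bg_draw = m & (u_bg < der.bg)

        dc = discount_factor(c, der.rate_cost)
        de = discount_factor(c, der.rate_effect)
        cost += dc * (
            hosp_ev * der.inpat[sev] + out_ev * der.outpat + pn_ev * der.pn_cost
        )

        survivors = m & ~die_ex & ~die_pn_draw & ~die_bg_draw
        detect_ev = survivors & ~is_det & (u_det < der.qdet[sev])

        treated = survivors & (is_det | detect_ev)
        untreated = survivors & ~is_det & ~detect_ev
        cost += dc * (
            treated * (der.drug[sev] + der.maint[sev])
            + detect_ev * der.confirm
            + untreated * der.cb
        )

        corr = np.ones(n)
        corr[out_ev] *= der.c_out
        corr[hosp_ev & ~die_ex] *= der.c_in
        corr[pn_ev & ~die_pn_draw] *= der.c_pn
        ly += de * survivors / 12.0
        qaly += de * survivors * der.u[sev] * corr / 12.0

        is_det = is_det | detect_ev
        fresh = detect_ev
        clock[fresh] = 0
        floor_sev[fresh] = sev[fresh]
        eff[fresh] = der.late_effect[sev[fresh]]
        dur[fresh] = der.late_duration
        alive = survivors

    result = ArmResult(
        arm=arm.name,
        total_cost=float(cost.mean()),
        life_years=float(ly.mean()),
        qalys=float(qaly.mean()),
        upfront_cost=float(upfront.mean()),
    )
    return MicrosimResult(
        result=result,
        per_patient_cost=cost,
        per_patient_qaly=qaly,
        per_patient_ly=ly,
    )
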