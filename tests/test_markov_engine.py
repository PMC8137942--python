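"""Cycle mechanics: probability conversions, mass conservation, event
accrual, and engine-level monotonicities."""

import numpy as np
import pytest

from copdscreen import (
    arms_from_parameters,
    entry_states,
    monthly_decline,
    monthly_prob,
    run_arm,
    run_arms,
    run_tree,
    step_cycle,
)
from copdscreen.parameters import update_parameters


def _zero_event_values():
    vals = {
        "clinical.severe_exacerbation_mortality": 0.0,
        "clinical.monthly_pneumonia_incidence": 0.0,
        "clinical.pneumonia_mortality": 0.0,
    }
    for sev in ("mild", "moderate", "severe"):
        vals[f"clinical.annual_exacerbation_prob.{sev}"] = 0.0
        vals[f"clinical.annual_detection_prob.{sev}"] = 0.0
    return vals


class TestConversions:
    @pytest.mark.parametrize(
        "annual,monthly",
        [(0.50, 0.056126), (0.90, 0.174596), (0.0, 0.0), (1.0, 1.0), (0.265, 0.025329)],
    )
    def test_monthly_prob_closed_form(self, annual, monthly):
        assert monthly_prob(annual) == pytest.approx(monthly, abs=5e-6)

    @pytest.mark.parametrize("annual", np.linspace(0.0, 0.999, 12).tolist())
    def test_inverse_round_trip(self, annual):
        assert 1.0 - (1.0 - monthly_prob(annual)) ** 12 == pytest.approx(
            annual, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_monthly_prob_domain(self, bad):
        with pytest.raises(ValueError):
            monthly_prob(bad)

    @pytest.mark.parametrize(
        "annual,monthly", [(0.041, 0.041 / 12), (0.0, 0.0), (0.049, 0.049 / 12)]
    )
    def test_monthly_decline(self, annual, monthly):
        assert monthly_decline(annual) == pytest.approx(monthly, abs=1e-12)


class TestStepCycle:
    def test_mass_conserved_every_cycle(self, params):
        arm = arms_from_parameters(params)["portable_spirometer"]
        result = run_arm(arm, params, horizon=120, collect_ledger=True)
        ledger = result.ledger
        alive_cols = [c for c in ledger.columns if c.startswith("alive_") and c != "alive_death"]
        total = ledger[alive_cols].sum(axis=1) + ledger["alive_death"]
        assert np.allclose(total, 1.0, atol=1e-9)
        assert (np.diff(ledger["alive_death"]) >= -1e-12).all()  # death absorbing

    def test_stationary_when_nothing_happens(self, params):
        vals = _zero_event_values()
        vals["clinical.fev1_decline_per_year"] = 0.0
        for reg in ("lama_laba", "laba_ics", "laba", "lama", "triple"):
            vals[f"clinical.treatment_effect_per_month.{reg}"] = 0.0
        frozen = update_parameters(params, vals)
        arm = arms_from_parameters(frozen)["questionnaire"]
        outcome = run_tree(arm, frozen.cohort, frozen.cost_utility)
        subs = entry_states(outcome, frozen)
        subs1, ledger1 = step_cycle(subs, frozen, cycle=1)
        subs2, ledger2 = step_cycle(subs1, frozen, cycle=2)
        assert ledger1.alive_by_state == pytest.approx(ledger2.alive_by_state)
        assert ledger1.costs == pytest.approx(ledger2.costs)
        assert ledger1.qalys == pytest.approx(ledger2.qalys)

    def test_hospital_exacerbation_month_utility(self, params):
        # a moderate patient-month spent in hospital accrues utility
        # 0.72 x 0.50; force every patient into that branch
        vals = _zero_event_values()
        vals.update(
            {
                "clinical.annual_exacerbation_prob.moderate": 1.0,
                "clinical.pct_exacerbation_hospital.moderate": 1.0,
            }
        )
        forced = update_parameters(params, vals)
        arm = arms_from_parameters(forced)["portable_spirometer"]
        outcome = run_tree(arm, forced.cohort, forced.cost_utility)
        subs = [
            s
            for s in entry_states(outcome, forced)
            if s.state.is_copd and s.state.severity == "moderate" and s.state.detected
        ]
        _, ledger = step_cycle(subs, forced, cycle=1)
        mass = sum(s.fraction for s in subs)
        assert ledger.qalys == pytest.approx(mass * 0.72 * 0.50 / 12.0)
        assert ledger.life_years == pytest.approx(mass / 12.0)


class TestRunArm:
    def test_horizon_zero_is_upfront_only(self, params):
        for name, arm in arms_from_parameters(params).items():
            result = run_arm(arm, params, horizon=0)
            assert result.total_cost == pytest.approx(result.upfront_cost)
            assert result.qalys == 0.0

    def test_no_screening_accrues_cb_treatment(self, base_results):
        assert base_results["no_screening"].cost_components["cb_treatment"] > 0
        assert base_results["no_screening"].cost_components["drug"] > 0  # late detection

    def test_discounted_not_above_undiscounted(self, base_results):
        for result in base_results.values():
            assert result.total_cost <= result.undiscounted["total_cost"] + 1e-9
            assert result.qalys <= result.undiscounted["qalys"] + 1e-12
            assert result.life_years <= result.undiscounted["life_years"] + 1e-12

    def test_qalys_bounded_by_life_years(self, base_results):
        for result in base_results.values():
            assert result.qalys <= result.life_years

    def test_zero_treatment_effect_equalizes_outcomes(self, params):
        # with no FEV1 benefit, detected and undetected trajectories are
        # identical, so arms differ only through costs
        vals = {
            f"clinical.treatment_effect_per_month.{r}": 0.0
            for r in ("lama_laba", "laba_ics", "laba", "lama", "triple")
        }
        # the decline pause during the effect window is itself a treatment
        # effect, so the window must be zeroed too
        vals["clinical.treatment_effect_duration"] = 0
        flat = update_parameters(params, vals)
        results = run_arms(flat)
        qalys = [r.qalys for r in results.values()]
        lys = [r.life_years for r in results.values()]
        assert max(qalys) - min(qalys) < 1e-9
        assert max(lys) - min(lys) < 1e-9
        costs = [r.total_cost for r in results.values()]
        assert max(costs) - min(costs) > 1.0

    def test_higher_exacerbation_mortality_lowers_life_years(self, params):
        arm = arms_from_parameters(params)["no_screening"]
        lys = []
        for mort in (0.005, 0.0128, 0.10):
            ps = update_parameters(
                params, {"clinical.severe_exacerbation_mortality": mort}
            )
            lys.append(run_arm(arm, ps).life_years)
        assert lys[0] >= lys[1] >= lys[2]
        assert lys[0] > lys[2]

    def test_background_mortality_shortens_life(self, params):
        arm = arms_from_parameters(params)["no_screening"]
        ps = update_parameters(params, {"clinical.background_mortality_annual": 0.02})
        assert run_arm(arm, ps).life_years < run_arm(arm, params).life_years
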