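"""Default parameter audit, file round-trips, one-way variants, and
probabilistic draws."""

import numpy as np
import pytest
from pydantic import ValidationError

from copdscreen import (
    PARAMETER_SPECS,
    ParameterSet,
    default_parameters,
    load_parameters,
    owsa_variants,
    sample_parameter_set,
    save_parameters,
)
from copdscreen.parameters import SEVERITIES, _draw, get_value

# Every published input cell: (dotted path, base, one-way low, one-way high).
PUBLISHED_CELLS = [
    ("screening.questionnaire.sensitivity", 0.8750, 0.7875, 0.9625),
    ("screening.questionnaire.specificity", 0.3880, 0.3492, 0.4268),
    ("screening.portable.sensitivity", 0.9990, 0.8991, 1.0000),
    ("screening.portable.specificity", 0.9770, 0.8793, 1.0000),
    ("cohort.copd_prevalence", 0.3137, 0.2510, 0.3764),
    ("cohort.severity_split.mild", 0.3138, 0.2510, 0.3765),
    ("cohort.severity_split.moderate", 0.4604, 0.3683, 0.5525),
    ("cohort.severity_split.severe", 0.2258, 0.1806, 0.2710),
    ("cohort.mean_age", 59.59, 47.67, 71.50),
    ("cohort.pct_female_copd", 0.2346, 0.1877, 0.2815),
    ("cohort.pct_female_noncopd", 0.3539, 0.2831, 0.4247),
    ("cohort.height_female", 155.80, 140.22, 171.38),
    ("cohort.height_male", 167.10, 150.39, 183.81),
    ("clinical.fev1_decline_per_year", 0.041, 0.033, 0.049),
    ("clinical.annual_detection_prob.mild", 0.20, 0.16, 0.24),
    ("clinical.annual_detection_prob.moderate", 0.50, 0.40, 0.60),
    ("clinical.annual_detection_prob.severe", 0.90, 0.72, 1.00),
    ("clinical.treatment_effect_per_month.lama_laba", 0.026, 0.021, 0.031),
    ("clinical.treatment_effect_per_month.laba_ics", 0.031, 0.025, 0.037),
    ("clinical.treatment_effect_per_month.laba", 0.013, 0.010, 0.016),
    ("clinical.treatment_effect_per_month.lama", 0.022, 0.018, 0.027),
    ("clinical.treatment_effect_per_month.triple", 0.025, 0.020, 0.030),
    ("clinical.annual_exacerbation_prob.mild", 0.190, 0.152, 0.228),
    ("clinical.annual_exacerbation_prob.moderate", 0.190, 0.152, 0.228),
    ("clinical.annual_exacerbation_prob.severe", 0.265, 0.212, 0.318),
    ("clinical.pct_exacerbation_hospital.mild", 0.6842, 0.5474, 0.8211),
    ("clinical.pct_exacerbation_hospital.moderate", 0.6842, 0.5474, 0.8211),
    ("clinical.pct_exacerbation_hospital.severe", 0.6604, 0.5283, 0.7925),
    ("clinical.severe_exacerbation_mortality", 0.0128, 0.0050, 0.1000),
    ("clinical.monthly_pneumonia_incidence", 0.0020, 0.0016, 0.0025),
    ("clinical.pneumonia_mortality", 0.0333, 0.0266, 0.0399),
    ("cost_utility.drug_cost_per_month.lama_laba", 642.0, 513.0, 770.0),
    ("cost_utility.drug_cost_per_month.laba_ics", 114.0, 91.0, 136.0),
    ("cost_utility.drug_cost_per_month.laba", 124.0, 99.0, 149.0),
    ("cost_utility.drug_cost_per_month.lama", 253.0, 202.0, 303.0),
    ("cost_utility.drug_cost_per_month.triple", 366.0, 292.0, 439.0),
    ("cost_utility.maintenance_cost_per_month.mild", 23.0, 18.0, 27.0),
    ("cost_utility.maintenance_cost_per_month.moderate", 67.0, 54.0, 81.0),
    ("cost_utility.maintenance_cost_per_month.severe", 187.0, 150.0, 225.0),
    ("cost_utility.cb_treatment_cost_per_month", 288.0, 100.0, 500.0),
    ("cost_utility.exacerbation_inpatient_cost.mild", 8639.0, 6911.0, 10366.0),
    ("cost_utility.exacerbation_inpatient_cost.moderate", 17277.0, 13822.0, 20732.0),
    ("cost_utility.exacerbation_inpatient_cost.severe", 25915.0, 20732.0, 31099.0),
    ("cost_utility.exacerbation_outpatient_cost", 395.0, 316.0, 474.0),
    ("cost_utility.pneumonia_cost", 32394.0, 25916.0, 38873.0),
    ("screening.portable.unit_cost", 34.0, 27.0, 41.0),
    ("screening.questionnaire.unit_cost", 8.0, 6.0, 9.0),
    ("cost_utility.confirmation_cost", 220.0, 176.0, 264.0),
    ("cost_utility.state_utility.mild", 0.81, 0.65, 0.97),
    ("cost_utility.state_utility.moderate", 0.72, 0.58, 0.86),
    ("cost_utility.state_utility.severe", 0.67, 0.54, 0.80),
    ("cost_utility.utility_correction_outpatient_exac", 0.85, 0.68, 0.99),
    ("cost_utility.utility_correction_inpatient_exac", 0.50, 0.40, 0.60),
    ("cost_utility.utility_correction_pneumonia", 0.50, 0.40, 0.60),
    ("cost_utility.discount_rate_cost", 0.035, 0.0, 0.05),
    ("cost_utility.discount_rate_effect", 0.035, 0.0, 0.05),
]


class TestDefaultAudit:
    def test_every_published_cell_present_exactly_once(self):
        spec_paths = [s.path for s in PARAMETER_SPECS]
        assert len(spec_paths) == len(set(spec_paths))
        assert sorted(spec_paths) == sorted(p for p, *_ in PUBLISHED_CELLS)

    @pytest.mark.parametrize("path,base,low,high", PUBLISHED_CELLS, ids=lambda v: str(v))
    def test_cell_values(self, params, path, base, low, high):
        spec = next(s for s in PARAMETER_SPECS if s.path == path)
        assert spec.base == pytest.approx(base, abs=1e-12)
        assert spec.low == pytest.approx(low, abs=1e-12)
        assert spec.high == pytest.approx(high, abs=1e-12)
        assert get_value(params, path) == pytest.approx(base, abs=1e-12)

    def test_severity_split_sums_to_one(self, params):
        assert sum(params.cohort.severity_split.values()) == pytest.approx(1.0, abs=1e-9)

    def test_treatment_mix_sums_to_one(self, params):
        for sev in SEVERITIES:
            assert sum(params.clinical.treatment_mix[sev].values()) == pytest.approx(1.0)


class TestFileRoundTrip:
    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_save_load_identity(self, params, tmp_path, ext):
        path = tmp_path / f"params.{ext}"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_out_of_range_sensitivity_rejected(self, params, tmp_path):
        data = params.model_dump(mode="json")
        data["screening"]["portable"]["sensitivity"] = 1.2
        path = tmp_path / "bad.json"
        import json

        path.write_text(json.dumps(data))
        with pytest.raises(ValidationError, match="sensitivity"):
            load_parameters(path)

    def test_missing_section_rejected(self, params, tmp_path):
        data = params.model_dump(mode="json")
        del data["cohort"]
        path = tmp_path / "missing.yaml"
        import yaml

        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ValidationError, match="cohort"):
            load_parameters(path)

    def test_bad_severity_split_rejected(self, params):
        data = params.model_dump()
        data["cohort"]["severity_split"]["mild"] = 0.9
        with pytest.raises(ValidationError, match="severity_split"):
            ParameterSet.model_validate(data)


class TestOwsaVariants:
    def test_one_pair_per_parameter(self, params):
        variants = owsa_variants(params)
        names = [name for name, *_ in variants]
        assert names == [s.path for s in PARAMETER_SPECS]

    @pytest.mark.parametrize(
        "path,lo,hi",
        [
            ("cohort.height_male", 150.39, 183.81),
            ("clinical.severe_exacerbation_mortality", 0.005, 0.10),
            ("clinical.fev1_decline_per_year", 0.033, 0.049),
        ],
    )
    def test_published_bounds_applied(self, params, path, lo, hi):
        variants = dict((n, (l, h)) for n, l, h in owsa_variants(params))
        low_ps, high_ps = variants[path]
        assert get_value(low_ps, path) == pytest.approx(lo)
        assert get_value(high_ps, path) == pytest.approx(hi)

    def test_only_named_parameter_differs(self, params):
        variants = owsa_variants(params)
        for name, low_ps, high_ps in variants:
            if name.startswith("cohort.severity_split."):
                # siblings are rescaled to keep the composition summing to 1
                assert sum(low_ps.cohort.severity_split.values()) == pytest.approx(1.0)
                assert sum(high_ps.cohort.severity_split.values()) == pytest.approx(1.0)
                continue
            for ps in (low_ps, high_ps):
                for other in PARAMETER_SPECS:
                    if other.path != name:
                        assert get_value(ps, other.path) == pytest.approx(
                            get_value(params, other.path)
                        ), f"{other.path} moved when varying {name}"

    def test_probabilities_stay_in_unit_interval(self, params):
        for name, low_ps, high_ps in owsa_variants(params):
            spec = next(s for s in PARAMETER_SPECS if s.path == name)
            if spec.group in ("probability", "utility"):
                assert 0.0 <= get_value(low_ps, name) <= 1.0
                assert 0.0 <= get_value(high_ps, name) <= 1.0


class TestSampling:
    def test_deterministic_given_seed(self, params):
        assert sample_parameter_set(params, seed=42) == sample_parameter_set(params, seed=42)
        assert sample_parameter_set(params, seed=42) != sample_parameter_set(params, seed=43)

    def test_fixed_parameters_keep_base(self, params):
        for seed in range(5):
            draw = sample_parameter_set(params, seed=seed)
            assert draw.cost_utility.discount_rate_cost == 0.035
            assert draw.cost_utility.discount_rate_effect == 0.035

    def test_supports_respected(self, params):
        for seed in range(30):
            draw = sample_parameter_set(params, seed=seed)
            for spec in PARAMETER_SPECS:
                v = get_value(draw, spec.path)
                if spec.group in ("probability", "utility"):
                    assert 0.0 <= v <= 1.0, spec.path
                else:
                    assert v >= 0.0, spec.path
            assert sum(draw.cohort.severity_split.values()) == pytest.approx(1.0, abs=1e-9)

    def test_beta_sample_mean_matches_base(self):
        # method-of-moments beta: sample mean of many draws sits at the base
        spec = next(
            s for s in PARAMETER_SPECS if s.path == "clinical.severe_exacerbation_mortality"
        )
        rng = np.random.default_rng(2024)
        draws = np.array([_draw(spec, rng) for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - spec.base) < 3 * se
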