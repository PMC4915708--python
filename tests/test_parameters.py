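"""Parameter containers, configuration loading, validation totality,
mortality-table construction and scenario application."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from copdcea.parameters import (
    DegenerateHazardError,
    LIVING_STAGES,
    MortalityModel,
    Override,
    ScenarioSpec,
    SchemaError,
    SeverityStage,
    SmokingStatus,
    TransitionModel,
    ValidationError,
    apply_scenario,
    build_mortality_model,
    load_parameters,
)
from copdcea.synthetic_data import baseline_document, make_transition_fixture


class TestStageEnum:
    def test_ordering_is_total_and_by_severity(self):
        assert SeverityStage.GOLD2 < SeverityStage.GOLD3 < SeverityStage.GOLD4 < SeverityStage.DEAD
        assert sorted(SeverityStage) == [
            SeverityStage.GOLD2, SeverityStage.GOLD3,
            SeverityStage.GOLD4, SeverityStage.DEAD]

    def test_death_is_terminal(self):
        assert SeverityStage.GOLD4.next_worse() is SeverityStage.DEAD
        with pytest.raises(ValueError):
            SeverityStage.DEAD.next_worse()

    def test_smoking_has_exactly_three_states(self):
        assert len(SmokingStatus) == 3


class TestLoadParameters:
    def test_baseline_values_verbatim(self, baseline):
        g2 = baseline.stage_params[SeverityStage.GOLD2]
        g4 = baseline.stage_params[SeverityStage.GOLD4]
        assert g2.annual_cost == 5398
        assert g2.utility_stable == 0.7511
        assert g2.utility_exacerbated == 0.7364
        assert g4.annual_cost == 10953
        assert baseline.smoking.relapse_prob == 0.026
        assert baseline.smoking.cessation_prob == 0.047
        assert baseline.pr_policy.utility_increment == 0.09
        assert baseline.pr_policy.annual_cost == 1583
        assert baseline.discount.annual_rate == 0.035
        np.testing.assert_allclose(
            baseline.cohort.stage_prevalence, [0.883, 0.105, 0.012])

    def test_out_of_range_probability_reported_with_path(self):
        doc = baseline_document()
        doc["stage_params"]["GOLD3"]["exacerbation_prob"] = 1.2
        with pytest.raises(ValidationError) as exc:
            load_parameters(doc)
        paths = [p for p, _ in exc.value.errors]
        assert "stage_params.GOLD3.exacerbation_prob" in paths

    def test_missing_stage_block_is_a_schema_error_naming_the_path(self):
        doc = baseline_document()
        del doc["stage_params"]["GOLD3"]
        with pytest.raises(SchemaError, match="stage_params.GOLD3"):
            load_parameters(doc)

    def test_round_trip_is_identity(self, baseline):
        doc = baseline.to_dict()
        again = load_parameters(doc)
        assert again.to_json() == baseline.to_json()
        assert again.digest() == baseline.digest()

    def test_yaml_round_trip(self, baseline, tmp_path):
        path = tmp_path / "params.yaml"
        baseline.to_yaml(path)
        assert load_parameters(path).digest() == baseline.digest()

    def test_validation_reports_every_violation_at_once(self):
        """Corrupt many fields, including deep table entries: every one must
        be reported with a locating path in a single error."""
        doc = baseline_document()
        doc = load_parameters(doc).to_dict()  # realized form with grids
        rng = np.random.default_rng(7)
        corrupted = []

        doc["stage_params"]["GOLD2"]["utility_stable"] = 1.8
        corrupted.append("stage_params.GOLD2.utility_stable")
        doc["smoking"]["relapse_prob"] = -0.1
        corrupted.append("smoking.relapse_prob")
        probs = doc["mortality"]["grid"]["probs"]
        for _ in range(3):
            i = int(rng.integers(len(probs)))
            j, k = int(rng.integers(3)), int(rng.integers(3))
            probs[i][j][k] = 5.0
            corrupted.append(f"mortality.q[age={i},stage={j},smoking={k}]")
        tp = doc["transitions"]["grid"]["probs"]
        tp[2][0][1][1] = -3.0
        corrupted.append("transitions.probs[band=2,stage=0,smoking=1,exacerbated=1]")

        with pytest.raises(ValidationError) as exc:
            load_parameters(doc)
        reported = {p for p, _ in exc.value.errors}
        for path in corrupted:
            assert path in reported, f"{path} not reported; got {reported}"

    def test_csv_table_dialects(self, baseline, tmp_path):
        """Pre-built transition and mortality tables round-trip through the
        published CSV dialects."""
        tcsv = tmp_path / "transitions.csv"
        mcsv = tmp_path / "mortality.csv"
        baseline.transitions.to_frame().to_csv(tcsv, index=False)
        baseline.mortality.to_frame().to_csv(mcsv, index=False)
        doc = baseline_document()
        doc["transitions"] = {"table": {"csv": str(tcsv)}}
        doc["mortality"] = {"table": {"csv": str(mcsv)}}
        loaded = load_parameters(doc)
        np.testing.assert_allclose(loaded.transitions.probs, baseline.transitions.probs)
        np.testing.assert_allclose(loaded.mortality.q, baseline.mortality.q)


class TestBuildMortalityModel:
    def test_closed_form_against_hazard_integration_oracle(self):
        """q'=1-exp(-HR*h) must agree with a fine-step product-integral of
        the scaled hazard."""
        q, hr_stage, hr_smoking = 0.01, 2.0, 1.5
        model = build_mortality_model(
            {60: q}, {s: hr_stage for s in LIVING_STAGES},
            {k: hr_smoking for k in SmokingStatus})
        got = model.prob(60, SeverityStage.GOLD2, SmokingStatus.NON_SMOKER)
        # 1 - exp(-HR * (-ln(1-q))) is identically 1 - (1-q)**HR
        assert got == pytest.approx(1 - 0.99**3.0, abs=1e-12)
        # independent oracle: Euler product of the constant scaled hazard
        h = -math.log(1 - q) * hr_stage * hr_smoking
        n = 1_000_000
        surv = (1 - h / n) ** n
        assert got == pytest.approx(1 - surv, abs=1e-7)

    def test_unit_hazard_ratios_are_identity(self):
        life = {a: 0.001 * (a - 59) for a in range(60, 70)}
        ones_s = {s: 1.0 for s in LIVING_STAGES}
        ones_k = {k: 1.0 for k in SmokingStatus}
        model = build_mortality_model(life, ones_s, ones_k)
        for a, qa in life.items():
            assert model.prob(a, SeverityStage.GOLD3, SmokingStatus.SMOKER) == pytest.approx(qa, rel=1e-12)

    def test_zero_probability_stays_zero(self):
        model = build_mortality_model(
            {50: 0.0}, {s: 7.0 for s in LIVING_STAGES},
            {k: 3.0 for k in SmokingStatus})
        assert model.q.max() == 0.0

    def test_hazard_ratio_composition_commutes(self):
        """Applying HR=a then HR=b equals applying HR=a*b directly."""
        life = {a: 0.002 * (a - 49) for a in range(50, 80)}
        a_hr, b_hr = 1.7, 2.3
        ones_k = {k: 1.0 for k in SmokingStatus}
        step1 = build_mortality_model(life, {s: a_hr for s in LIVING_STAGES}, ones_k)
        qs1 = {age: step1.prob(age, SeverityStage.GOLD2, SmokingStatus.NON_SMOKER)
               for age in life}
        step2 = build_mortality_model(qs1, {s: b_hr for s in LIVING_STAGES}, ones_k)
        direct = build_mortality_model(
            life, {s: a_hr * b_hr for s in LIVING_STAGES}, ones_k)
        for age in life:
            assert step2.prob(age, SeverityStage.GOLD2, SmokingStatus.NON_SMOKER) == pytest.approx(
                direct.prob(age, SeverityStage.GOLD2, SmokingStatus.NON_SMOKER), abs=1e-12)

    def test_monotone_in_stage_for_increasing_hazard_ratios(self, baseline):
        q = baseline.mortality.q
        assert np.all(q[:, 1, :] >= q[:, 0, :])
        assert np.all(q[:, 2, :] >= q[:, 1, :])

    def test_degenerate_probability_rejected(self):
        with pytest.raises(DegenerateHazardError):
            build_mortality_model({60: 1.0}, {s: 2.0 for s in LIVING_STAGES},
                                  {k: 1.0 for k in SmokingStatus})

    def test_missing_age_coverage_rejected(self):
        with pytest.raises(SchemaError, match="coverage"):
            build_mortality_model({a: 0.01 for a in range(30, 80)},
                                  {s: 1.0 for s in LIVING_STAGES},
                                  {k: 1.0 for k in SmokingStatus},
                                  max_age=110)


class TestTransitionModel:
    def test_nearest_band_lookup_clamps(self):
        t = make_transition_fixture(seed=1)
        lo = t.prob(SeverityStage.GOLD2, 20, SmokingStatus.SMOKER, False)
        assert lo == t.prob(SeverityStage.GOLD2, 40, SmokingStatus.SMOKER, False)
        hi = t.prob(SeverityStage.GOLD2, 105, SmokingStatus.SMOKER, False)
        assert hi == t.prob(SeverityStage.GOLD2, 89, SmokingStatus.SMOKER, False)

    def test_gold4_never_progresses(self):
        t = make_transition_fixture(seed=3)
        assert t.prob(SeverityStage.GOLD4, 70, SmokingStatus.SMOKER, True) == 0.0


class TestApplyScenario:
    def test_halving_rehabilitation_cost(self, baseline):
        spec = ScenarioSpec("PR cost -50%",
                            (Override("pr_policy.annual_cost", 0.5, "mul"),))
        out = apply_scenario(baseline, spec)
        assert out.pr_policy.annual_cost == 791.5
        assert baseline.pr_policy.annual_cost == 1583  # input untouched

    def test_setting_utility_increment(self, baseline):
        spec = ScenarioSpec("low benefit",
                            (Override("pr_policy.utility_increment", 0.03),))
        assert apply_scenario(baseline, spec).pr_policy.utility_increment == 0.03

    def test_empty_scenario_is_identity(self, baseline):
        out = apply_scenario(baseline, ScenarioSpec("noop"))
        assert out.to_json() == baseline.to_json()

    def test_application_is_pure_and_repeatable(self, baseline):
        spec = ScenarioSpec("exac", (Override("pr_policy.exacerbation_multiplier", 0.54),))
        first = apply_scenario(baseline, spec).to_json()
        second = apply_scenario(baseline, spec).to_json()
        assert first == second

    def test_unresolvable_path_rejected(self, baseline):
        spec = ScenarioSpec("bad", (Override("pr_policy.no_such_knob", 1.0),))
        with pytest.raises(SchemaError, match="no_such_knob"):
            apply_scenario(baseline, spec)

    def test_invalid_override_value_rejected(self, baseline):
        spec = ScenarioSpec("bad", (Override("smoking.cessation_prob", 1.7),))
        with pytest.raises(ValidationError):
            apply_scenario(baseline, spec)
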