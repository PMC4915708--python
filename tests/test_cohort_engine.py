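"""Microsimulation and deterministic evaluator: within-cycle accounting,
trajectory invariants, common random numbers, and oracle equivalence."""

import dataclasses

import numpy as np
import pytest

from copdcea.cohort_engine import (
    PatientState,
    UnsupportedConfigurationError,
    _EngineTables,
    _run_patient_fast,
    advance_cycle,
    draw_initial_state,
    evaluate_cohort,
    simulate_cohort,
    simulate_patient,
)
from copdcea.parameters import (
    MortalityModel,
    PRPolicy,
    SeverityStage,
    SmokingStatus,
)
from copdcea.synthetic_data import UncertaintySpec, sample_parameters

from conftest import make_toy_params


def g2_patient(age=60):
    return PatientState(age=age, stage=SeverityStage.GOLD2,
                        smoking=SmokingStatus.NON_SMOKER)


class TestAdvanceCycle:
    def test_dead_patient_is_absorbing_with_zero_accrual(self, baseline):
        dead = PatientState(age=70, stage=SeverityStage.DEAD,
                            smoking=SmokingStatus.SMOKER, alive=False)
        state, record = advance_cycle(dead, baseline, "usual_care",
                                      np.random.default_rng(0))
        assert not state.alive
        assert record.utility_accrued == 0.0
        assert record.cost_accrued == 0.0
        assert not record.alive_at_start

    def test_usual_care_accruals_without_exacerbation(self, baseline):
        """A stable GOLD2 usual-care year accrues the stable utility and the
        stage's annual cost."""
        params = dataclasses.replace(baseline)
        # force the no-exacerbation outcome
        doc = baseline.to_dict()
        for stage in doc["stage_params"].values():
            stage["exacerbation_prob"] = 0.0
        from copdcea.parameters import load_parameters
        params = load_parameters(doc)
        _, record = advance_cycle(g2_patient(), params, "usual_care",
                                  np.random.default_rng(1))
        assert record.utility_accrued == 0.7511
        assert record.cost_accrued == 5398

    def test_pr_accruals_with_exacerbation(self, baseline):
        """An exacerbated GOLD2 rehabilitation year accrues the exacerbated
        utility plus the program increment, and both cost components."""
        doc = baseline.to_dict()
        for stage in doc["stage_params"].values():
            stage["exacerbation_prob"] = 1.0
        from copdcea.parameters import load_parameters
        params = load_parameters(doc)
        _, record = advance_cycle(g2_patient(), params, "pr",
                                  np.random.default_rng(1))
        assert record.utility_accrued == pytest.approx(0.7364 + 0.09, abs=1e-12)
        assert record.cost_accrued == pytest.approx(5398 + 1583, abs=1e-9)


class TestSimulatePatient:
    def test_certain_death_gives_exactly_one_cycle(self):
        params = make_toy_params(q=1.0)
        traj = simulate_patient(g2_patient(), params, "usual_care",
                                np.random.default_rng(0))
        assert len(traj.records) == 1
        assert traj.life_years == 1.0

    def test_degenerate_dynamics_run_to_the_age_cap(self):
        params = make_toy_params(q=0.0, max_age=80)
        traj = simulate_patient(g2_patient(age=60), params, "usual_care",
                                np.random.default_rng(0))
        assert len(traj.records) == 80 - 60
        assert traj.records[-1].stage is SeverityStage.GOLD2

    def test_stage_sequence_never_improves(self, baseline):
        """Unidirectional progression over many random-parameter
        trajectories."""
        rng = np.random.default_rng(2024)
        unc = UncertaintySpec()
        order = {SeverityStage.GOLD2: 0, SeverityStage.GOLD3: 1,
                 SeverityStage.GOLD4: 2}
        for _ in range(20):
            params = sample_parameters(baseline, unc, rng)
            for i in range(100):
                g = np.random.default_rng((7, i))
                initial = draw_initial_state(params, g)
                traj = simulate_patient(initial, params, "pr", g)
                stages = [order[r.stage] for r in traj.records]
                assert stages == sorted(stages)
                assert traj.n_exacerbated_cycles == sum(
                    r.exacerbated for r in traj.records)

    def test_fast_path_matches_record_level_path(self, baseline):
        """The accrual-only inner loop must be draw-for-draw identical to
        the record-producing one."""
        t = _EngineTables(baseline, "pr")
        r = baseline.discount.annual_rate
        for i in range(30):
            g1 = np.random.default_rng((5, i))
            initial = draw_initial_state(baseline, g1)
            traj = simulate_patient(initial, baseline, "pr", g1)

            g2 = np.random.default_rng((5, i))
            g2.random(3)  # skip the initial-state draws consumed above
            from copdcea.parameters import stage_index
            ly, qaly, cost, _ = _run_patient_fast(
                t, initial.age, stage_index(initial.stage), int(initial.smoking), g2)
            exp_qaly = sum(rec.utility_accrued * (1 + r) ** -rec.cycle_index
                           for rec in traj.records)
            exp_cost = sum(rec.cost_accrued * (1 + r) ** -rec.cycle_index
                           for rec in traj.records)
            assert ly == traj.life_years
            assert qaly == pytest.approx(exp_qaly, rel=1e-12)
            assert cost == pytest.approx(exp_cost, rel=1e-12)


class TestSimulateCohort:
    def test_same_seed_is_bitwise_identical(self, baseline):
        a = simulate_cohort(baseline, "pr", 500, seed=11)
        b = simulate_cohort(baseline, "pr", 500, seed=11)
        assert a == b

    def test_invalid_cohort_size_rejected(self, baseline):
        with pytest.raises(ValueError):
            simulate_cohort(baseline, "pr", 0, seed=1)

    def test_common_random_numbers_give_zero_life_year_difference(self, baseline):
        uc = simulate_cohort(baseline, "usual_care", 2000, seed=3)
        pr = simulate_cohort(baseline, "pr", 2000, seed=3)
        assert pr.mean_ly - uc.mean_ly == 0.0

    def test_qaly_equals_ly_with_unit_utility_and_no_discounting(self):
        params = make_toy_params(q=0.1, utility=(1.0, 1.0), rate=0.0,
                                 exac_prob=0.3)
        res = simulate_cohort(params, "usual_care", 500, seed=5)
        assert res.mean_qaly == pytest.approx(res.mean_ly, rel=1e-12)


class TestEvaluateCohort:
    def test_geometric_series_life_expectancy(self):
        """Constant q=1/2, one stage: LY = sum of 0.5^k = 2."""
        params = make_toy_params(q=0.5)
        res = evaluate_cohort(params, "usual_care")
        assert res.mean_ly == pytest.approx(2.0, rel=1e-12)

    def test_mass_is_conserved_every_cycle(self, baseline):
        _, audit = evaluate_cohort(baseline, "pr", return_audit=True)
        assert audit["max_mass_error"] <= 1e-12

    def test_discounted_person_years_match_between_arms(self, baseline):
        uc = evaluate_cohort(baseline, "usual_care")
        pr = evaluate_cohort(baseline, "pr")
        assert uc.discounted_person_years == pr.discounted_person_years
        assert uc.mean_ly == pr.mean_ly

    def test_history_dependent_dynamics_are_rejected(self, baseline):
        doc = baseline.to_dict()
        doc["exacerbation_history_multiplier"] = 1.1
        from copdcea.parameters import load_parameters
        params = load_parameters(doc)
        with pytest.raises(UnsupportedConfigurationError):
            evaluate_cohort(params, "usual_care")

    def test_higher_mortality_weakly_decreases_life_years(self, baseline):
        base = evaluate_cohort(baseline, "usual_care").mean_ly
        worse_q = np.clip(baseline.mortality.q * 1.5, 0, 1)
        worse = dataclasses.replace(baseline)
        worse.mortality = MortalityModel(baseline.mortality.age_min, worse_q)
        assert evaluate_cohort(worse, "usual_care").mean_ly < base

    def test_qaly_non_increasing_in_discount_rate(self, baseline):
        from copdcea.parameters import load_parameters
        qalys = []
        for rate in (0.0, 0.035, 0.07):
            doc = baseline.to_dict()
            doc["discount"]["annual_rate"] = rate
            qalys.append(evaluate_cohort(load_parameters(doc), "pr").mean_qaly)
        assert qalys[0] > qalys[1] > qalys[2]

    def test_microsim_agrees_with_oracle_within_monte_carlo_error(self, baseline):
        """The deterministic evaluator is the microsimulation's expected
        value: means agree within 3 Monte Carlo SEs."""
        det = evaluate_cohort(baseline, "usual_care")
        sim = simulate_cohort(baseline, "usual_care", 20_000, seed=17)
        assert abs(sim.mean_ly - det.mean_ly) <= 3 * sim.se_ly
        assert abs(sim.mean_qaly - det.mean_qaly) <= 3 * sim.se_qaly
        assert abs(sim.mean_cost - det.mean_cost) <= 3 * sim.se_cost
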