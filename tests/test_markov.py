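"""Transition-matrix construction and the cohort engine."""

import numpy as np
import pytest

from afibcea import states
from afibcea.markov import (
    EngineError,
    build_transition_matrix,
    lifetime_ablations,
    run_cycles,
    run_markov,
    time_in_states,
)
from afibcea.microsim import run_microsim
from afibcea.tree import run_decision_tree


def uniform_living():
    occ = np.full(states.N_STATES, 1.0 / (states.N_STATES - 1))
    occ[states.DEAD] = 0.0
    return occ


class TestTransitionMatrix:
    def test_zero_risks_give_identity(self, zero_risk_params):
        p = zero_risk_params.copy()
        p.risks.ablation_success = 0.0  # irrelevant once reablation is 0
        M, aux = build_transition_matrix(p, "aad", 60.0)
        assert np.allclose(M, np.eye(states.N_STATES), atol=1e-14)
        assert np.all(aux.p_death == 0.0)

    @pytest.mark.parametrize("arm", ["cryoablation", "aad"])
    @pytest.mark.parametrize("age", [57.5, 70.0, 90.0])
    def test_rows_are_stochastic(self, base_params, arm, age):
        M, _ = build_transition_matrix(base_params, arm, age, hf_prevalence=0.1)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0.0) and np.all(M <= 1.0)

    def test_dead_row_is_absorbing(self, base_params):
        M, _ = build_transition_matrix(base_params, "aad", 60.0)
        expected = np.zeros(states.N_STATES)
        expected[states.DEAD] = 1.0
        assert np.array_equal(M[states.DEAD], expected)

    def test_substate_index_never_decreases(self, base_params):
        M, _ = build_transition_matrix(base_params, "aad", 60.0)
        for i in states.LIVING:
            for j in states.LIVING:
                if states.group_of(j) != "PERM" and states.substate_of(j) < states.substate_of(i):
                    assert M[i, j] == 0.0, f"{states.STATES[i]} -> {states.STATES[j]}"

    def test_no_direct_jump_nsr_to_permanent(self, base_params):
        M, _ = build_transition_matrix(base_params, "aad", 60.0)
        for k in range(4):
            assert M[states.NSR[k], states.PERM] == 0.0

    def test_permanent_exits_only_to_death(self, base_params):
        M, _ = build_transition_matrix(base_params, "cryoablation", 60.0)
        for j in range(states.N_STATES):
            if j not in (states.PERM, states.DEAD):
                assert M[states.PERM, j] == 0.0

    def test_reablation_blocked_at_lifetime_cap(self, base_params):
        # cryo: index + 2 repeats -> no ablation from k=2; AAD: none from k=3
        M_cryo, aux_cryo = build_transition_matrix(base_params, "cryoablation", 60.0)
        M_aad, aux_aad = build_transition_matrix(base_params, "aad", 60.0)
        assert aux_cryo.p_reablation[states.ST[2]] == 0.0
        assert aux_cryo.p_reablation[states.ST[1]] > 0.0
        assert aux_aad.p_reablation[states.ST[3]] == 0.0
        assert aux_aad.p_reablation[states.ST[2]] > 0.0
        assert M_cryo[states.ST[2], states.NSR[3]] == 0.0
        assert M_aad[states.ST[2], states.NSR[3]] > 0.0

    def test_rr_multipliers_scale_recurrence(self, base_params):
        p = base_params.copy()
        p.risks.stroke_annual_by_score = {k: 0.0 for k in p.risks.stroke_annual_by_score}
        M, aux = build_transition_matrix(p, "aad", 60.0)
        rec = p.risks.recurrence["aad"]
        for k in range(4):
            surv = 1.0 - aux.p_death[states.NSR[k]]
            expected = surv * rec * p.risks.rr_recurrence_by_count[k]
            assert M[states.NSR[k], states.ST[k]] == pytest.approx(expected, abs=1e-12)

    def test_probability_products_capped_at_one(self, base_params):
        p = base_params.copy()
        p.risks.recurrence["aad"] = 0.9
        p.risks.rr_recurrence_by_count = [1.0, 2.0, 2.0, 2.0]  # would exceed 1
        M, _ = build_transition_matrix(p, "aad", 60.0)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M <= 1.0)

    def test_arm_symmetry_of_engine_without_reablation(self, base_params):
        # equal arm-labelled inputs and no ablation pathway: the engine must
        # treat the arm label as inert
        p = base_params.copy()
        p.risks.recurrence["cryoablation"] = p.risks.recurrence["aad"]
        p.risks.resolution["cryoablation"] = p.risks.resolution["aad"]
        p.risks.reablation = {"ST": {"cryoablation": 0.0, "aad": 0.0},
                              "LT": {"cryoablation": 0.0, "aad": 0.0}}
        for cat in p.risks.utilization.values():
            cat["cryoablation"] = cat["aad"]
        M1, _ = build_transition_matrix(p, "cryoablation", 70.0)
        M2, _ = build_transition_matrix(p, "aad", 70.0)
        assert np.array_equal(M1, M2)

    def test_blanking_redirects_ablation_failures_to_nsr(self, base_params):
        p = base_params.copy()
        p.settings.blanking_period_active = True
        Mb, auxb = build_transition_matrix(p, "aad", 60.0)
        M, aux = build_transition_matrix(base_params, "aad", 60.0)
        s = states.ST[0]
        assert Mb[s, states.ST[1]] == 0.0
        assert Mb[s, states.NSR[1]] == pytest.approx(
            M[s, states.NSR[1]] + M[s, states.ST[1]], abs=1e-12
        )
        assert auxb.p_blanked[s] > 0.0
        assert np.all(aux.p_blanked == 0.0)

    def test_negative_input_rejected(self, base_params):
        p = base_params.copy()
        p.risks.recurrence["aad"] = -0.1
        with pytest.raises(EngineError, match="negative"):
            build_transition_matrix(p, "aad", 60.0)


class TestCohortEngine:
    def test_all_dead_allocation_stays_dead_with_zero_accruals(self, base_params):
        occ0 = np.zeros(states.N_STATES)
        occ0[states.DEAD] = 1.0
        trace = run_cycles(base_params, "aad", occ0, n_cycles=8, start_age=60.0, global_offset=0)
        assert np.all(trace.occupancy[:, states.DEAD] == 1.0)
        assert trace.qaly_undisc.sum() == 0.0
        assert all(arr.sum() == 0.0 for arr in trace.cost_undisc.values())

    def test_identity_transitions_keep_occupancy_constant(self, zero_risk_params):
        occ0 = uniform_living()
        trace = run_cycles(zero_risk_params, "aad", occ0, n_cycles=12, start_age=60.0,
                           global_offset=0)
        assert np.allclose(trace.occupancy, occ0[None, :], atol=1e-12)

    def test_occupancy_conservation_and_dead_monotonicity(self, base_result):
        for run in (base_result.intervention, base_result.comparator):
            run.trace.check_invariants()
            assert np.allclose(run.trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = run.trace.occupancy[:, states.DEAD]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_time_in_states_definition(self, zero_risk_params):
        occ0 = np.zeros(states.N_STATES)
        occ0[states.NSR[0]] = 1.0
        trace = run_cycles(zero_risk_params, "aad", occ0, n_cycles=4, start_age=60.0,
                           global_offset=0)
        tis = time_in_states(trace)
        assert tis["NSR"] == pytest.approx(1.0)
        assert tis["ST"] == tis["LT"] == tis["PERM"] == tis["DEAD"] == 0.0

    def test_time_in_states_partitions_horizon(self, base_result):
        for run in (base_result.intervention, base_result.comparator):
            tis = time_in_states(run.trace)
            horizon = run.trace.n_cycles * 0.25
            assert sum(tis.values()) == pytest.approx(horizon, abs=1e-9)

    def test_relative_change_arithmetic_matches_reported_convention(self):
        # e.g. 2.08 years gained on a 19.91-year baseline is a +10.4% change
        gained, base = 2.08, 19.91
        assert round(100 * gained / base, 1) == 10.4

    def test_lifetime_ablations_zero_without_reablation(self, zero_risk_params):
        alloc = run_decision_tree(zero_risk_params, "cryoablation")
        trace = run_markov(zero_risk_params, alloc, "cryoablation")
        counts = lifetime_ablations(trace, alloc)
        assert counts["twelve_months"] == 0.0
        assert counts["horizon"] == 0.0

    def test_lifetime_ablations_monotone_in_reablation_rate(self, base_params):
        values = []
        for rate in (0.01, 0.03, 0.06, 0.10):
            p = base_params.copy()
            p.risks.reablation["ST"]["aad"] = rate
            alloc = run_decision_tree(p, "aad")
            trace = run_markov(p, alloc, "aad")
            values.append(lifetime_ablations(trace, alloc)["horizon"])
        assert values == sorted(values)
        assert all(v < 3.0 for v in values)

    def test_horizon_count_at_least_twelve_month_count(self, base_result):
        for run in (base_result.intervention, base_result.comparator):
            counts = lifetime_ablations(run.trace, run.allocation)
            assert counts["horizon"] >= counts["twelve_months"]

    def test_raising_recurrence_rr_increases_af_state_years(self, base_params):
        af_years = []
        for mult in (0.8, 1.0, 1.3, 1.7):
            p = base_params.copy()
            p.risks.rr_recurrence_by_count = [
                min(3.0, r * mult) for r in p.risks.rr_recurrence_by_count
            ]
            p.risks.recurrence = {a: v for a, v in p.risks.recurrence.items()}
            alloc = run_decision_tree(p, "aad")
            trace = run_markov(p, alloc, "aad")
            tis = time_in_states(trace)
            af_years.append(tis["ST"] + tis["LT"] + tis["PERM"])
        assert af_years == sorted(af_years)
        assert af_years[0] < af_years[-1]


class TestMicrosimOracle:
    def test_cohort_trace_matches_individual_simulation(self, base_params):
        # moderate scale for the unit suite; the acceptance suite runs the
        # full-size comparison on several parameter sets
        occ0 = np.zeros(states.N_STATES)
        occ0[states.NSR[0]] = 0.6
        occ0[states.ST[0]] = 0.4
        n_cycles, n_walkers = 60, 30_000
        trace = run_cycles(base_params, "aad", occ0, n_cycles=n_cycles, start_age=58.5,
                           global_offset=4)
        micro = run_microsim(base_params, "aad", occ0, n_cycles=n_cycles, start_age=58.5,
                             n_walkers=n_walkers, seed=11)
        for cycle in (10, 30, 60):
            for grp, members in states.GROUP_MEMBERS.items():
                cohort = trace.occupancy[cycle, list(members)].sum()
                sampled = micro.occupancy[cycle, list(members)].sum()
                tol = 3.0 * np.sqrt(cohort * (1.0 - cohort) / n_walkers) + 1e-9
                assert abs(cohort - sampled) <= tol, (cycle, grp)
        # cumulative expected ablations agree within Monte-Carlo error
        assert abs(trace.ablations.sum() - micro.mean_ablation_count) <= (
            3.0 * micro.se_ablation_count + 1e-9
        )
        assert abs(trace.strokes.sum() - micro.mean_stroke_count) <= (
            3.0 * micro.se_stroke_count + 1e-9
        )
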