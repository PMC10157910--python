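"""Cohort engine: transition structure, rewards, traces, and oracles."""

import numpy as np
import pytest

import sarcocea as sc
from sarcocea.cohort_model import (
    Arm,
    HealthState,
    build_transition_row,
    combined_fall_risk_reduction,
    cycle_rewards,
    run_arm,
    run_strategy,
)
from sarcocea.parameters import ParameterSet, StrategySpec
from sarcocea.synthetic_data import make_toy_scenario, random_scenario


class TestFallRiskCombination:
    def test_no_intervention_zero(self):
        assert combined_fall_risk_reduction(StrategySpec(name="None")) == 0.0

    def test_single_indicator_full_reduction(self):
        # vitamin D reports only muscle-performance improvement
        d = StrategySpec(name="D", frr_mp=27.08)
        assert combined_fall_risk_reduction(d) == pytest.approx(0.2708)

    def test_indicators_sum(self):
        pd = StrategySpec(name="P+D", frr_mm=46.52, frr_ms=1.6, frr_mp=20.1)
        assert combined_fall_risk_reduction(pd) == pytest.approx(0.6822)

    def test_capped_at_one(self):
        s = StrategySpec(name="max", frr_mm=60.0, frr_ms=60.0, frr_mp=60.0)
        assert combined_fall_risk_reduction(s) == 1.0


class TestTransitionRows:
    def test_dead_absorbing(self, reference_config, life_table):
        params, strategies = reference_config
        row = build_transition_row(
            HealthState.DEAD, 80, Arm.OFF_TREATMENT, strategies[0], params,
            life_table,
        )
        assert np.array_equal(row, [0, 0, 0, 1])

    def test_off_treatment_sarcopenic_at_60(self, reference_config, life_table):
        params, strategies = reference_config
        row = build_transition_row(
            HealthState.SARCOPENIC, 60, Arm.OFF_TREATMENT, strategies[0],
            params, life_table,
        )
        assert row[HealthState.DEAD] == pytest.approx(0.0151566249, abs=1e-9)
        assert row[HealthState.FRACTURE_YEAR] == pytest.approx(
            0.0503747386, abs=1e-9
        )
        assert row[HealthState.SARCOPENIC] == pytest.approx(0.9344686364, abs=1e-9)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_on_treatment_d_strategy_fracture_probability(
        self, reference_config, life_table
    ):
        params, strategies = reference_config
        d = {s.name: s for s in strategies}["D"]
        row = build_transition_row(
            HealthState.SARCOPENIC, 60, Arm.ON_TREATMENT, d, params, life_table
        )
        p_die = 0.0151566249
        expected = (1 - p_die) * 0.155 * (1 - 0.2708) * 0.33
        assert row[HealthState.FRACTURE_YEAR] == pytest.approx(expected, abs=1e-9)

    def test_fracture_year_routes_to_post_fracture(
        self, reference_config, life_table
    ):
        params, strategies = reference_config
        row = build_transition_row(
            HealthState.FRACTURE_YEAR, 60, Arm.OFF_TREATMENT, strategies[0],
            params, life_table,
        )
        assert row[HealthState.DEAD] == pytest.approx(0.0954714225, abs=1e-9)
        assert row[HealthState.POST_FRACTURE] == pytest.approx(
            1 - 0.0954714225, abs=1e-9
        )
        assert row[HealthState.SARCOPENIC] == 0.0

    @pytest.mark.parametrize("state", list(HealthState))
    @pytest.mark.parametrize("arm", list(Arm))
    def test_rows_are_distributions(self, state, arm, reference_config, life_table):
        params, strategies = reference_config
        for strat in strategies:
            for age in (60, 75, 90, 109):
                row = build_transition_row(
                    state, age, arm, strat, params, life_table
                )
                assert np.all(row >= 0)
                assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_age_outside_table_rejected(self, reference_config, life_table):
        params, strategies = reference_config
        with pytest.raises(Exception, match="outside"):
            build_transition_row(
                HealthState.SARCOPENIC, 111, Arm.OFF_TREATMENT, strategies[0],
                params, life_table,
            )


class TestCycleRewards:
    def test_dead_zero(self, reference_config):
        params, strategies = reference_config
        assert cycle_rewards(
            HealthState.DEAD, Arm.ON_TREATMENT, strategies[1], params
        ) == (0.0, 0.0)

    def test_off_treatment_fracture_year(self, reference_config):
        params, strategies = reference_config
        cost, utility = cycle_rewards(
            HealthState.FRACTURE_YEAR, Arm.OFF_TREATMENT, strategies[0], params
        )
        assert cost == pytest.approx(12_588.214)
        assert utility == pytest.approx(0.785 - 0.25)

    def test_on_treatment_sarcopenic_under_protein(self, reference_config):
        params, strategies = reference_config
        p = {s.name: s for s in strategies}["P"]
        cost, utility = cycle_rewards(
            HealthState.SARCOPENIC, Arm.ON_TREATMENT, p, params
        )
        assert cost == pytest.approx(5_463.329 + 400.409)
        assert utility == pytest.approx(0.785)

    def test_intervention_cost_not_charged_after_fracture(self, reference_config):
        # the strategy cost attaches to the managed pre-fracture state
        params, strategies = reference_config
        p = {s.name: s for s in strategies}["P"]
        cost_fy, _ = cycle_rewards(HealthState.FRACTURE_YEAR, Arm.ON_TREATMENT,
                                   p, params)
        cost_pf, _ = cycle_rewards(HealthState.POST_FRACTURE, Arm.ON_TREATMENT,
                                   p, params)
        assert cost_fy == pytest.approx(12_588.214)
        assert cost_pf == pytest.approx(2_517.64)


class TestRunArm:
    def test_annuity_closed_form(self):
        toy = make_toy_scenario("no-events")
        trace = run_arm(toy.strategy, Arm.OFF_TREATMENT, toy.params,
                        toy.life_table)
        assert trace.discounted_qalys == pytest.approx(toy.expected_qalys,
                                                       abs=1e-10)
        assert trace.discounted_cost == 0.0

    def test_zero_discount_equals_undiscounted_sum(self, reference_config,
                                                   life_table):
        params, strategies = reference_config
        flat = params.with_values(discount_rate_costs=0.0,
                                  discount_rate_outcomes=0.0)
        trace = run_arm(strategies[0], Arm.OFF_TREATMENT, flat, life_table)
        occ = trace.occupancy[:-1]
        u = np.array([0.785, 0.535, 0.615, 0.0])
        assert trace.discounted_qalys == pytest.approx(float((occ @ u).sum()),
                                                       rel=1e-12)

    def test_conservation_and_absorption(self, reference_config, life_table):
        params, strategies = reference_config
        for strat in strategies:
            for arm in Arm:
                trace = run_arm(strat, arm, params, life_table)
                sums = trace.occupancy.sum(axis=1)
                assert np.all(np.abs(sums - 1.0) < 1e-9)
                dead = trace.occupancy[:, HealthState.DEAD]
                assert np.all(np.diff(dead) >= -1e-15)
                assert dead[-1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_matrix_propagation(self, reference_config, life_table):
        """The unrolled engine equals generic propagation through
        build_transition_row matrices."""
        params, strategies = reference_config
        d = {s.name: s for s in strategies}["D"]
        for arm in Arm:
            trace = run_arm(d, arm, params, life_table)
            occ = np.zeros(4)
            occ[HealthState.SARCOPENIC] = 1.0
            for t in range(trace.n_cycles):
                assert np.allclose(trace.occupancy[t], occ, atol=1e-12)
                matrix = np.stack(
                    [
                        build_transition_row(s, 60 + t, arm, d, params,
                                             life_table)
                        for s in HealthState
                    ]
                )
                occ = occ @ matrix
            assert np.allclose(trace.occupancy[-1], occ, atol=1e-12)


class TestRunStrategy:
    def test_full_acceptance_equals_on_arm(self, reference_config, life_table):
        params, strategies = reference_config
        d = {s.name: s for s in strategies}["D"].with_values(acceptance=1.0)
        outcome = run_strategy(d, params, life_table)
        on = run_arm(d, Arm.ON_TREATMENT, params, life_table)
        assert outcome.discounted_cost == pytest.approx(on.discounted_cost)
        assert outcome.discounted_qalys == pytest.approx(on.discounted_qalys)

    def test_zero_acceptance_equals_off_arm(self, reference_config, life_table):
        params, strategies = reference_config
        d = {s.name: s for s in strategies}["D"].with_values(acceptance=0.0)
        outcome = run_strategy(d, params, life_table)
        off = run_arm(d, Arm.OFF_TREATMENT, params, life_table)
        assert outcome.discounted_cost == pytest.approx(off.discounted_cost)
        assert outcome.discounted_qalys == pytest.approx(off.discounted_qalys)

    def test_treatment_reduces_lifetime_fractures(self, reference_config,
                                                  life_table):
        params, strategies = reference_config
        by_name = {s.name: s for s in strategies}
        none = run_strategy(by_name["None"], params, life_table)
        d = run_strategy(by_name["D"], params, life_table)
        assert d.fracture_years < none.fracture_years

    def test_effect_monotonicity_in_frr(self, reference_config, life_table):
        """More fall-risk reduction never yields fewer QALYs."""
        params, _ = reference_config
        base = StrategySpec(name="x", annual_cost=100.0, acceptance=0.9)
        prev = -np.inf
        for frr in (0.0, 10.0, 25.0, 50.0, 90.0):
            outcome = run_strategy(base.with_values(frr_mp=frr), params,
                                   life_table)
            assert outcome.discounted_qalys >= prev
            prev = outcome.discounted_qalys


class TestMicrosimAgreement:
    def test_base_case_off_arm(self, reference_config, life_table):
        params, strategies = reference_config
        trace = run_arm(strategies[0], Arm.OFF_TREATMENT, params, life_table)
        sim = sc.microsim_oracle(
            strategies[0], Arm.OFF_TREATMENT, params, life_table,
            n_paths=60_000, seed=5,
        )
        assert abs(sim.qalys - trace.discounted_qalys) < 3 * sim.qalys_se
        assert abs(sim.cost - trace.discounted_cost) < 3 * sim.cost_se

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_random_scenarios(self, seed):
        rng = np.random.default_rng(seed)
        params, strategies = random_scenario(rng, n_strategies=2)
        strat = strategies[1]
        lt = sc.gompertz_life_table(
            q_anchor=params.q60_background, slope=0.09, max_age=105
        )
        for arm in Arm:
            trace = run_arm(strat, arm, params, lt)
            sim = sc.microsim_oracle(strat, arm, params, lt,
                                     n_paths=30_000, seed=seed + 1)
            assert abs(sim.qalys - trace.discounted_qalys) < 3 * sim.qalys_se
            assert abs(sim.cost - trace.discounted_cost) < 3 * sim.cost_se
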