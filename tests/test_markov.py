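"""Cohort propagation, transition assembly, discounting and accrual."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oligocea as o
from oligocea.markov import (
    TransitionSchedule,
    state_cycle_cost,
    state_cycle_utility,
)
from oligocea.params import HealthState, ParameterEstimate
from oligocea.survival import WeibullFit

from conftest import flat_schedule, toy_schedules


def fixed(mean):
    return ParameterEstimate(float(mean))


class TestRunCohort:
    def test_geometric_absorption(self):
        # constant 0.5 death probability: Death occupancy 0.5, 0.75, 0.875
        M = np.tile(np.array([[0.5, 0.5], [0.0, 1.0]]), (3, 1, 1))
        trans = TransitionSchedule(states=["Alive", "Death"], matrices=M)
        trace = o.run_cohort(trans, "Alive", 3)
        assert np.allclose(trace.occupancy[:, 1], [0.0, 0.5, 0.75, 0.875])

    def test_permutation_dynamics_returns_to_start(self):
        P = np.roll(np.eye(3), 1, axis=1)
        trans = TransitionSchedule(states=["a", "b", "c"], matrices=np.tile(P, (6, 1, 1)))
        trace = o.run_cohort(trans, "a", 6)
        assert np.allclose(trace.occupancy[3], trace.occupancy[0])
        assert np.allclose(trace.occupancy[6], trace.occupancy[0])

    def test_symmetric_chain_converges_to_uniform(self):
        M = np.tile(np.full((2, 2), 0.5), (60, 1, 1))
        trace = o.run_cohort(TransitionSchedule(states=["x", "y"], matrices=M), "x", 60)
        assert np.allclose(trace.occupancy[-1], [0.5, 0.5])

    def test_non_stochastic_matrix_rejected(self):
        M = np.tile(np.array([[0.5, 0.4], [0.0, 1.0]]), (2, 1, 1))
        with pytest.raises(ValueError, match="non-stochastic"):
            TransitionSchedule(states=["a", "b"], matrices=M)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_conservation_for_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        S, K = 4, 12
        M = rng.dirichlet(np.ones(S), size=(K, S))
        M[:, -1, :] = 0.0
        M[:, -1, -1] = 1.0
        trace = o.run_cohort(TransitionSchedule(states=list("abcd"), matrices=M), "a", K)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, -1]) >= -1e-12)


class TestAssembleTransitions:
    def make_arm(self, **overrides):
        states = overrides.pop("states", (
            HealthState("Alive", progression_from_pfs=True, cost=fixed(100),
                        utility=ParameterEstimate(0.8, 0.0, "fixed")),
            HealthState("Progression", cost=fixed(200), utility=fixed(0.5)),
            HealthState("Death", absorbing=True),
        ))
        return o.ArmConfig(name="A", states=states, initial_state="Alive", **overrides)

    def test_identity_schedules_freeze_the_cohort(self):
        arm = self.make_arm()
        sched = flat_schedule(0.0, 8)
        trans = o.assemble_transitions(arm, sched, sched)
        trace = o.run_cohort(trans, "Alive", 8)
        assert np.allclose(trace.occupancy[:, 0], 1.0)

    def test_alive_fraction_matches_weibull_survival(self):
        # only OS-driven death: the alive fraction is the survival function
        fit = WeibullFit(1.47, 35.9)
        horizon, c = 5.0, 3.0
        os_sched = o.build_schedule(fit, horizon, c, 60.0)
        trans = o.assemble_transitions(self.make_arm(), os_sched, os_sched)
        trace = o.run_cohort(trans, "Alive", 20)
        alive = 1.0 - trace.occupancy[:, 2]
        expected = o.survival_at(fit, np.arange(21) * c)
        assert np.allclose(alive, expected, atol=1e-9)

    def test_pfs_below_os_clamps_progression(self):
        arm = self.make_arm()
        os_sched = flat_schedule(0.3, 4)
        pfs_sched = flat_schedule(0.1, 4)  # composite event "rarer" than death
        trans = o.assemble_transitions(arm, os_sched, pfs_sched)
        assert np.all(trans.matrices[:, 0, 1] == 0.0)

    def test_transient_state_empties_after_entry_cycle(self):
        states = (
            HealthState("Treat", transient=True, events=(
                o.EventVariant("ok", ParameterEstimate(0.9, 0.0, "fixed"),
                               fixed(10), fixed(0.7), destination="Alive"),
                o.EventVariant("bad", ParameterEstimate(0.1, 0.0, "fixed"),
                               fixed(20), fixed(0.4), destination="Progression"),
            )),
            HealthState("Alive", progression_from_pfs=True, cost=fixed(100),
                        utility=fixed(0.8)),
            HealthState("Progression", cost=fixed(200), utility=fixed(0.5)),
            HealthState("Death", absorbing=True),
        )
        arm = o.ArmConfig(name="A", states=states, initial_state="Treat")
        sched = flat_schedule(0.05, 10)
        trans = o.assemble_transitions(arm, sched, flat_schedule(0.15, 10))
        trace = o.run_cohort(trans, "Treat", 10)
        assert np.all(trace.occupancy[1:, 0] == 0.0)
        # survivors split 0.9/0.1 between Alive and Progression at entry
        assert trace.occupancy[1, 1] == pytest.approx(0.95 * 0.9)
        assert trace.occupancy[1, 2] == pytest.approx(0.95 * 0.1)

    def test_event_destination_routes_residual_share(self):
        states = (
            HealthState("Alive", progression_from_pfs=True, events=(
                o.EventVariant("none", ParameterEstimate(0.95, 0.0, "fixed"),
                               fixed(10), fixed(0.8)),
                o.EventVariant("major", ParameterEstimate(0.05, 0.0, "fixed"),
                               fixed(50), fixed(0.5), destination="Progression"),
            )),
            HealthState("Progression", cost=fixed(200), utility=fixed(0.5)),
            HealthState("Death", absorbing=True),
        )
        arm = o.ArmConfig(name="A", states=states, initial_state="Alive")
        trans = o.assemble_transitions(arm, flat_schedule(0.1, 2), flat_schedule(0.25, 2))
        # row: death 0.1, progression 0.15 + residual 0.75 * 0.05
        assert trans.matrices[0, 0, 2] == pytest.approx(0.1)
        assert trans.matrices[0, 0, 1] == pytest.approx(0.15 + 0.75 * 0.05)
        assert trans.matrices[0, 0, 0] == pytest.approx(0.75 * 0.95)

    def test_mismatched_grids_rejected(self):
        arm = self.make_arm()
        with pytest.raises(ValueError, match="grid"):
            o.assemble_transitions(arm, flat_schedule(0.1, 4), flat_schedule(0.1, 5))


class TestDiscountFactor:
    def test_reference_rate_one_year(self):
        assert o.discount_factor(0.015, 1.0) == pytest.approx(1 / 1.015)

    def test_degenerate_cases(self):
        assert o.discount_factor(0.0, 7.5) == 1.0
        assert o.discount_factor(0.015, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            o.discount_factor(-0.01, 1.0)


class TestAccumulate:
    def alive_forever_trace(self, n_cycles=20):
        occ = np.zeros((n_cycles + 1, 2))
        occ[:, 0] = 1.0
        return o.MarkovTrace(states=["Alive", "Death"], occupancy=occ, cycle_length=3.0)

    def states(self, utility=1.0):
        return [HealthState("Alive", cost=fixed(0.0), utility=fixed(utility)),
                HealthState("Death", absorbing=True)]

    def test_full_survival_gives_horizon_years(self):
        res = o.accumulate(self.alive_forever_trace(), self.states(1.0), rate=0.0)
        assert res.total_ly == pytest.approx(5.0)
        assert res.total_qaly == pytest.approx(5.0)
        assert res.total_cost == 0.0

    def test_utility_weighting(self):
        res = o.accumulate(self.alive_forever_trace(), self.states(0.78), rate=0.0)
        assert res.total_qaly == pytest.approx(5.0 * 0.78)

    def test_discounting_reduces_totals(self):
        states = self.states(1.0)
        r0 = o.accumulate(self.alive_forever_trace(), states, rate=0.0)
        r1 = o.accumulate(self.alive_forever_trace(), states, rate=0.015)
        r2 = o.accumulate(self.alive_forever_trace(), states, rate=0.05)
        assert r0.total_qaly == r0.undiscounted_qaly
        assert r2.total_qaly < r1.total_qaly < r0.total_qaly
        assert r1.undiscounted_qaly == r0.undiscounted_qaly
        # closed form: sum of (1.015)^(-k/4) quarter-years
        expected = 0.25 * np.sum(1.015 ** (-np.arange(20) * 0.25))
        assert r1.total_qaly == pytest.approx(expected, rel=1e-12)

    def test_one_time_cost_charged_on_entry(self):
        M = np.tile(np.array([[0.0, 1.0], [0.0, 1.0]]), (2, 1, 1))
        trans = TransitionSchedule(states=["Start", "Death"], matrices=M)
        trace = o.run_cohort(trans, "Start", 2)
        states = [HealthState("Start", one_time_cost=fixed(500.0), utility=fixed(0.5)),
                  HealthState("Death", absorbing=True)]
        res = o.accumulate(trace, states, rate=0.0, transitions=trans)
        assert res.total_cost == pytest.approx(500.0)
        assert res.total_qaly == pytest.approx(0.5 * 0.25)

    def test_expected_event_cost_and_utility(self):
        s = HealthState("Alive", events=(
            o.EventVariant("a", ParameterEstimate(0.7, 0.0, "fixed"), fixed(100), fixed(0.8)),
            o.EventVariant("b", ParameterEstimate(0.3, 0.0, "fixed"), fixed(200), fixed(0.6)),
        ))
        assert state_cycle_cost(s) == pytest.approx(130.0)
        assert state_cycle_utility(s) == pytest.approx(0.74)

    def test_half_cycle_correction_flag(self):
        M = np.tile(np.array([[0.5, 0.5], [0.0, 1.0]]), (4, 1, 1))
        trans = TransitionSchedule(states=["Alive", "Death"], matrices=M)
        trace = o.run_cohort(trans, "Alive", 4)
        states = self.states(1.0)
        plain = o.accumulate(trace, states, rate=0.0)
        hcc = o.accumulate(trace, states, rate=0.0, half_cycle_correction=True)
        # trapezoid accrual credits half a cycle less at the front
        assert hcc.total_ly < plain.total_ly
        expected = 0.25 * np.sum(0.5 * (trace.occupancy[:-1, 0] + trace.occupancy[1:, 0]))
        assert hcc.total_ly == pytest.approx(expected)

    def test_identical_runs_are_bitwise_equal(self, toy_config):
        sched = toy_schedules(toy_config)
        arm = toy_config.intervention
        trans = o.assemble_transitions(arm, sched["intervention"]["os"],
                                       sched["intervention"]["pfs"])
        trace = o.run_cohort(trans, arm.initial_state, 20)
        r1 = o.accumulate(trace, arm.states, 0.015, transitions=trans)
        r2 = o.accumulate(trace, arm.states, 0.015, transitions=trans)
        assert (r1.total_cost, r1.total_qaly, r1.total_ly) == \
               (r2.total_cost, r2.total_qaly, r2.total_ly)
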