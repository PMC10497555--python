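"""Stochastic-engine tests: primitives, bookkeeping, evolution rules,
determinism, and the compiled-kernel equivalence."""

import math

import numpy as np
import pytest
from scipy import stats

from paccsim import (
    ConfigError,
    DrugSchedule,
    EventRates,
    Interval,
    ModelParameters,
    PopulationState,
    ResistanceTraits,
    RngPolicy,
    apply_event,
    draw_waiting_time,
    fitness,
    make_schedule,
    make_scenario,
    propose_and_resolve_mutation,
    select_event,
    simulate_trial,
)
from paccsim.engine import QUIESCENT
from paccsim.experiments import run_replicates


class TestWaitingTime:
    def test_mean_matches_inverse_rate(self, rng):
        total = 2.0
        draws = [draw_waiting_time(total, rng) for _ in range(100_000)]
        mean = np.mean(draws)
        se = np.std(draws) / math.sqrt(len(draws))
        assert abs(mean - 0.5) < 3 * se

    def test_high_rate_short_waits(self, rng):
        assert draw_waiting_time(1e12, rng) < 1e-9

    def test_reproducible(self):
        a = draw_waiting_time(1.0, np.random.RandomState(5))
        b = draw_waiting_time(1.0, np.random.RandomState(5))
        assert a == b

    def test_zero_rate_signals_quiescence(self, rng):
        assert draw_waiting_time(0.0, rng) is QUIESCENT

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ConfigError):
            draw_waiting_time(-1.0, rng)


class TestSelectEvent:
    def test_degenerate_distribution(self, rng):
        r = EventRates(birth_N=1.0)
        assert all(select_event(r, rng) == "birth_N" for _ in range(100))

    def test_two_channel_frequencies(self, rng):
        r = EventRates(birth_N=1.0, death_P=1.0)
        n = 100_000
        counts = {"birth_N": 0, "death_P": 0}
        for _ in range(n):
            counts[select_event(r, rng)] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-4

    def test_zero_rate_channels_never_selected(self, rng):
        r = EventRates(birth_N=0.3, death_N=0.7, switch_P_to_R=0.0)
        assert {select_event(r, rng) for _ in range(500)} <= {"birth_N", "death_N"}

    def test_all_zero_is_error(self, rng):
        with pytest.raises(ConfigError):
            select_event(EventRates(), rng)


class TestApplyEvent:
    @pytest.mark.parametrize("state, event, expected", [
        ((0, 1, 0), "switch_P_to_R", (0, 0, 2)),     # depoly: 1 PACC -> 2 daughters
        ((5, 0, 0), "birth_N", (6, 0, 0)),
        ((5, 0, 3), "switch_R_to_N", (6, 0, 2)),
        ((5, 2, 3), "death_P", (5, 1, 3)),
        ((5, 2, 3), "birth_R", (5, 2, 4)),
    ])
    def test_bookkeeping(self, state, event, expected):
        out = apply_event(PopulationState(*state), event)
        assert out.as_tuple() == expected

    def test_depoly_reroutes_to_sensitive(self):
        out = apply_event(PopulationState(0, 1, 0), "switch_P_to_R",
                          depoly_to_sensitive=True)
        assert out.as_tuple() == (2, 0, 0)

    def test_failed_pat_loses_the_cell(self):
        rng = np.random.RandomState(0)
        outcomes = {apply_event(PopulationState(5, 0, 0), "switch_N_to_P",
                                rng=rng, zeta=0.7).as_tuple()
                    for _ in range(200)}
        assert outcomes == {(4, 1, 0), (4, 0, 0)}

    def test_empty_source_is_invariant_violation(self):
        with pytest.raises(AssertionError):
            apply_event(PopulationState(0, 0, 0), "death_N")


class TestMutationRule:
    def setup_method(self):
        self.params = ModelParameters()
        self.state = PopulationState(30, 5, 5)
        self.sc = make_scenario("temporary_innate_resistance")

    def test_frozen_without_drug(self):
        rng = np.random.RandomState(1)
        t = ResistanceTraits((0.5, 0.2))
        for _ in range(200):
            assert propose_and_resolve_mutation(
                t, 0.01, (0.0, 0.0), self.params, self.state, rng, self.sc) is t

    def test_negative_increments_purged(self):
        accepted = []
        rng = np.random.RandomState(2)
        for _ in range(3000):
            out = propose_and_resolve_mutation(
                ResistanceTraits(), 0.01, (0.7, 0.0), self.params, self.state,
                rng, self.sc, "division")
            if out.v[0] > 0:
                accepted.append(out.v[0])
        assert accepted                      # some positive mutants do fix
        assert min(accepted) > 0             # and never a negative step

    def test_division_targets_active_drug_only(self):
        rng = np.random.RandomState(3)
        for _ in range(3000):
            out = propose_and_resolve_mutation(
                ResistanceTraits(), 0.01, (0.0, 0.7), self.params, self.state,
                rng, self.sc, "division")
            assert out.v[0] == 0.0           # inactive drug's trait untouched

    def test_depoly_targets_either_drug_but_fixes_only_active(self):
        rng = np.random.RandomState(4)
        fixed = [propose_and_resolve_mutation(
                    ResistanceTraits(), 0.05, (0.7, 0.0), self.params,
                    self.state, rng, self.sc, "depolyploidization").v
                 for _ in range(6000)]
        v1_hits = sum(v[0] > 0 for v in fixed)
        v2_hits = sum(v[1] > 0 for v in fixed)
        assert v2_hits == 0                  # inactive-trait mutants are neutral -> purged
        # roughly phi * 1/2 (target draw) * 1/2 (positive step) of proposals fix
        expected = 6000 * self.params.phi * 0.25
        assert abs(v1_hits - expected) < 5 * math.sqrt(expected)

    def test_acceptance_equals_strict_fitness_improvement(self, rng):
        """The implemented accept rule (targeted drug active and step > 0)
        coincides with a strict resident-vs-mutant comparison of the
        susceptible-state invasion fitness, across scenarios and states."""
        for name in ("single_state", "pacc_no_R", "pacc_memory",
                     "innate_resistance", "temporary_innate_resistance"):
            sc = make_scenario(name)
            p = sc.resolve()
            for _ in range(200):
                state = PopulationState(rng.randint(1, 120),
                                        rng.randint(0, 30) * sc.enable_pacc,
                                        rng.randint(0, 30) * sc.enable_resistant)
                doses = (rng.choice([0.0, 0.7]), rng.choice([0.0, 0.7]))
                v = ResistanceTraits((rng.uniform(0, 3), rng.uniform(0, 3)))
                i = rng.randint(0, 2)
                delta = rng.normal(0, 0.05)
                if v.v[i] + delta < 0:
                    continue
                mutant = v.bumped(i, delta)
                f_res = fitness(state, v, p, scenario=sc, compartment="N", doses=doses)
                f_mut = fitness(state, mutant, p, scenario=sc, compartment="N",
                                doses=doses)
                shortcut = delta > 0 and doses[i] > 0
                assert shortcut == (f_mut > f_res)

    def test_unknown_pathway(self):
        with pytest.raises(ConfigError):
            propose_and_resolve_mutation(ResistanceTraits(), 0.01, (0.7, 0.0),
                                         self.params, self.state,
                                         np.random.RandomState(0), self.sc, "bogus")


#: legal per-event changes in (N, P, R)
_ALLOWED_DELTAS = {
    "birth_N": {(1, 0, 0)},
    "birth_R": {(0, 0, 1)},
    "death_N": {(-1, 0, 0)},
    "death_P": {(0, -1, 0)},
    "death_R": {(0, 0, -1)},
    "switch_N_to_P": {(-1, 1, 0), (-1, 0, 0)},       # failed PAT loses the cell
    "switch_R_to_P": {(0, 1, -1), (0, 0, -1)},
    "switch_P_to_R": {(0, -1, 2), (2, -1, 0)},       # +2 N when R is disabled
    "switch_R_to_N": {(1, 0, -1)},
}


class TestSimulateTrial:
    def test_empty_start_is_extinct_at_zero(self, schedule_same):
        traj = simulate_trial(make_scenario("pacc_no_R"), schedule_same,
                              initial_state=PopulationState(0, 0, 0))
        assert traj.extinct and traj.extinction_time == 0.0

    def test_traits_frozen_without_therapy(self, drug_free_schedule):
        traj = simulate_trial(make_scenario("temporary_innate_resistance"),
                              drug_free_schedule, seed=3)
        assert traj.final_traits.v == (0.0, 0.0)
        assert all(v.v == (0.0, 0.0) for v in traj.traits)

    def test_event_bookkeeping_and_trait_monotonicity(self, schedule_different):
        """Replay every recorded event: compartment deltas match the event
        catalogue, counts stay non-negative, traits never decrease, and
        traits only move while a drug is active."""
        boundaries = [(100, 400), (500, 800)]
        for name in ("pacc_no_R", "pacc_memory", "temporary_innate_resistance"):
            traj = simulate_trial(make_scenario(name), schedule_different, seed=42)
            assert traj.n_events == len(traj.times) > 100
            assert all(a < b for a, b in zip(traj.times, traj.times[1:]))
            prev_s, prev_v = traj.initial_state, traj.initial_traits
            for t, ev, s, v in zip(traj.times, traj.events, traj.states, traj.traits):
                delta = tuple(int(b - a) for a, b in
                              zip(prev_s.as_tuple(), s.as_tuple()))
                assert delta in _ALLOWED_DELTAS[ev], (ev, delta)
                assert min(s.as_tuple()) >= 0
                assert v.v[0] >= prev_v.v[0] and v.v[1] >= prev_v.v[1]
                if v.v != prev_v.v:
                    assert any(a <= t < b for a, b in boundaries)
                prev_s, prev_v = s, v

    def test_seed_determinism(self, schedule_same):
        sc = make_scenario("pacc_memory")
        a = simulate_trial(sc, schedule_same, seed=9)
        b = simulate_trial(sc, schedule_same, seed=9)
        assert a.times == b.times and a.events == b.events
        assert a.final_traits == b.final_traits

    def test_extinction_is_terminal_and_recorded(self, schedule_same):
        sc = make_scenario("single_state")      # m=0.7: certain extinction
        traj = simulate_trial(sc, schedule_same, seed=1)
        assert traj.extinct
        assert traj.final_state.total == 0
        assert 100 < traj.extinction_time < 400     # during the first window
        assert traj.final_time == traj.extinction_time

    def test_event_log_export(self, schedule_same):
        traj = simulate_trial(make_scenario("pacc_no_R"), schedule_same, seed=2)
        frame = traj.to_frame()
        assert list(frame.columns) == ["time", "event", "N", "P", "R", "v1", "v2"]
        assert frame.iloc[0]["event"] == "init"
        assert len(frame) == traj.n_events + 1


class TestRngPolicy:
    def test_distinct_streams(self):
        pol = RngPolicy(7)
        seeds = {pol.trial_seed(s, t) for s in range(10) for t in range(100)}
        assert len(seeds) == 1000
        assert all(0 <= s < 2**31 for s in seeds)

    def test_matrix_matches_scalar_derivation(self):
        pol = RngPolicy(3)
        mat = pol.seed_matrix(3, 4)
        assert mat[2, 1] == pol.trial_seed(2, 1)


class TestKernelEquivalence:
    def test_bit_identical_to_python_engine(self, all_scenarios, schedule_different):
        """The numba batch kernel and the pure-Python engine must produce
        bit-identical per-trial outcomes under the same seed policy."""
        for sc in all_scenarios:
            rp = run_replicates(sc, schedule_different, n_sets=1, n_trials=3,
                                base_seed=11, engine="python")
            rc = run_replicates(sc, schedule_different, n_sets=1, n_trials=3,
                                base_seed=11, engine="compiled")
            for col in ("extinct", "N", "P", "R", "v1", "v2", "n_events"):
                assert (rp.trials[col].to_numpy() == rc.trials[col].to_numpy()).all(), \
                    (sc.name, col)
            a = rp.trials["extinction_time"].fillna(-1.0).to_numpy()
            b = rc.trials["extinction_time"].fillna(-1.0).to_numpy()
            assert (a == b).all(), sc.name


def test_quiescent_population_jumps_to_horizon():
    """A configuration with zero total propensity advances through schedule
    boundaries without consuming random draws."""
    sched = DrugSchedule(intervals=(Interval(0, 10), Interval(10, 20)))
    sc = make_scenario("single_state", r=0.0)       # no birth, no drug -> no events
    traj = simulate_trial(sc, sched, seed=0,
                          initial_state=PopulationState(5, 0, 0))
    assert traj.n_events == 0
    assert not traj.extinct
    assert traj.final_state.N == 5
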