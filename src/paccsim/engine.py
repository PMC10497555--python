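"""Exact stochastic simulation of the birth-death-switching process.

One resident population is simulated with the Gillespie algorithm over the
nine event channels read from :mod:`paccsim.rates`. Propensities are
piecewise constant in time between events but change discontinuously at
therapy-schedule boundaries; the engine keeps the simulation exact by
discarding any tentative event whose waiting time overshoots the next
boundary and restarting the clock there.

Evolution follows adaptive-dynamics trait substitution: at each division
(breadth ``sigma1``) or depolyploidization (breadth ``sigma2``) a mutation
arises with probability ``phi`` while a drug is active. Division mutations
target the active drug's resistance trait; depolyploidization mutations
target a uniformly chosen drug trait (the PACC pathway supplies larger but
undirected variation). A mutant that strictly improves invasion fitness
through the susceptible state replaces the resident trait immediately
(invasion implies substitution); all others — including every mutation on
an inactive drug's trait, which is selectively neutral — are purged. Traits
are therefore frozen during drug holidays and non-decreasing along every
trajectory.

Random draws come from a NumPy legacy ``RandomState`` stream; the draw
order per event is part of the reproducibility contract and is mirrored
exactly by the compiled batch kernel in :mod:`paccsim._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .params import (
    ConfigError,
    DrugSchedule,
    EventRates,
    EVENT_ORDER,
    ModelParameters,
    PopulationState,
    ResistanceTraits,
)
from .rates import compute_event_rates
from .scenarios import ScenarioConfig

__all__ = [
    "RngPolicy",
    "Trajectory",
    "draw_waiting_time",
    "select_event",
    "apply_event",
    "propose_and_resolve_mutation",
    "simulate_trial",
]


QUIESCENT = math.inf
"""Sentinel returned by :func:`draw_waiting_time` when the total rate is zero."""


@dataclass(frozen=True)
class RngPolicy:
    """Deterministic derivation of independent per-trial random streams.

    Each (set, trial) pair maps to its own 31-bit seed through a
    ``SeedSequence`` spawn key, so any partition of the trials over
    workers reproduces the serial results bit-for-bit.
    """

    base_seed: int

    def trial_seed(self, set_index: int, trial_index: int) -> int:
        ss = np.random.SeedSequence(self.base_seed,
                                    spawn_key=(set_index, trial_index))
        return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF

    def seed_matrix(self, n_sets: int, n_trials: int) -> np.ndarray:
        return np.array([[self.trial_seed(s, t) for t in range(n_trials)]
                         for s in range(n_sets)], dtype=np.int64)


@dataclass
class Trajectory:
    """Full event history of one stochastic trial.

    ``times``/``events``/``states``/``traits`` are parallel per-event
    records (the initial condition is stored separately); ``extinct`` is
    set when the total population first hits zero, which is absorbing.
    """

    initial_state: PopulationState
    initial_traits: ResistanceTraits
    times: List[float] = field(default_factory=list)
    events: List[str] = field(default_factory=list)
    states: List[PopulationState] = field(default_factory=list)
    traits: List[ResistanceTraits] = field(default_factory=list)
    extinct: bool = False
    extinction_time: Optional[float] = None
    final_time: float = 0.0
    final_state: PopulationState = None  # type: ignore[assignment]
    final_traits: ResistanceTraits = None  # type: ignore[assignment]
    n_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy event log: time, event, N, P, R, v1, v2 (initial row included)."""
        rows = [(0.0, "init", *self.initial_state.as_tuple(), *self.initial_traits.v)]
        rows += [(t, e, *s.as_tuple(), *v.v)
                 for t, e, s, v in zip(self.times, self.events, self.states, self.traits)]
        return pd.DataFrame(rows, columns=["time", "event", "N", "P", "R", "v1", "v2"])

    def summary(self) -> dict:
        return {
            "extinct": self.extinct,
            "extinction_time": self.extinction_time,
            "final_time": self.final_time,
            "N": self.final_state.N, "P": self.final_state.P, "R": self.final_state.R,
            "v1": self.final_traits.v[0], "v2": self.final_traits.v[1],
            "n_events": self.n_events,
        }


def draw_waiting_time(total_rate: float, rng: np.random.RandomState) -> float:
    """Exponential waiting time with mean 1 / total_rate.

    A zero total rate signals quiescence and returns ``inf`` without
    consuming a draw (the caller jumps to the next schedule boundary).
    """
    if not math.isfinite(total_rate) or total_rate < 0:
        raise ConfigError(f"total rate must be finite and >= 0, got {total_rate}")
    if total_rate == 0.0:
        return QUIESCENT
    return float(rng.exponential(1.0 / total_rate))


def select_event(rates: EventRates, rng: np.random.RandomState) -> str:
    """Choose one of the nine channels with probability rate / total."""
    total = rates.total
    if total <= 0:
        raise ConfigError("select_event requires a positive total rate")
    u = rng.random_sample() * total
    acc = 0.0
    for name in EVENT_ORDER:
        acc += getattr(rates, name)
        if u < acc:
            return name
    return EVENT_ORDER[-1]  # guard against accumulated round-off


def apply_event(state: PopulationState, event: str,
                rng: Optional[np.random.RandomState] = None,
                zeta: float = 1.0,
                depoly_to_sensitive: bool = False) -> PopulationState:
    """Bookkeeping for one executed event.

    Births add one cell; deaths remove one. A switch into the PACC state
    removes the source cell and adds a PACC cell only with probability
    ``zeta`` (a failed polyaneuploid transition is mitotic catastrophe and
    the cell is lost). Depolyploidization replaces one PACC cell with two
    proliferative daughters — 2N+(R) cells, or 2N+ cells when the
    resistant state is disabled.
    """
    N, P, R = state.N, state.P, state.R

    def bern_success() -> bool:
        if zeta >= 1.0:
            return True
        if rng is None:
            raise ConfigError("zeta < 1 requires an rng for the PAT success draw")
        return rng.random_sample() < zeta

    if event == "birth_N":
        N += 1
    elif event == "birth_R":
        R += 1
    elif event == "death_N":
        N -= 1
    elif event == "death_P":
        P -= 1
    elif event == "death_R":
        R -= 1
    elif event == "switch_N_to_P":
        N -= 1
        if bern_success():
            P += 1
    elif event == "switch_R_to_P":
        R -= 1
        if bern_success():
            P += 1
    elif event == "switch_P_to_R":
        P -= 1
        if depoly_to_sensitive:
            N += 2
        else:
            R += 2
    elif event == "switch_R_to_N":
        R -= 1
        N += 1
    else:
        raise ConfigError(f"unknown event {event!r}")
    if min(N, P, R) < 0:
        raise AssertionError(f"event {event} applied to empty source compartment")
    return PopulationState(N, P, R)


def propose_and_resolve_mutation(traits: ResistanceTraits, breadth: float,
                                 doses: Tuple[float, ...],
                                 params: ModelParameters,
                                 state: PopulationState,
                                 rng: np.random.RandomState,
                                 scenario: Optional[ScenarioConfig] = None,
                                 pathway: str = "division") -> ResistanceTraits:
    """Mutation-and-substitution step at a division or depolyploidization.

    With probability ``phi`` (and only while some drug is active) a mutant
    trait vector is proposed by adding a Normal(0, breadth) increment to
    one resistance trait. A division mutation is shaped by the selective
    pressure of ongoing therapy and targets the active drug's trait
    (uniform among active drugs if several); a depolyploidization mutation
    arises from the drug-agnostic genomic upheaval of the PACC state and
    targets a uniformly chosen drug trait, active or not.

    The mutant replaces the resident iff it strictly improves invasion
    fitness through the susceptible 2N+ state (whose rate constants are
    trait-independent). That per-capita growth rate is strictly increasing
    in an active drug's trait and flat in an inactive one, so acceptance
    reduces exactly to "targeted drug active and increment positive";
    ties — in particular every mutation on an inactive trait — are purged.
    Traits never change during drug holidays. Equivalence of this rule to
    the explicit resident-vs-mutant :func:`paccsim.rates.fitness`
    comparison is pinned by the test suite.
    """
    if pathway not in ("division", "depolyploidization"):
        raise ConfigError(f"unknown mutation pathway {pathway!r}")
    active = [i for i, m in enumerate(doses) if m > 0]
    if not active:
        return traits
    if rng.random_sample() >= params.phi:
        return traits
    if pathway == "division":
        candidates = active
    else:
        candidates = list(range(len(doses)))
    if len(candidates) == 1:
        i = candidates[0]
    else:
        i = candidates[0] if rng.random_sample() < 0.5 else candidates[1]
    delta = float(rng.normal(0.0, breadth))
    if delta > 0.0 and i in active:
        return traits.bumped(i, delta)
    return traits


def simulate_trial(scenario: ScenarioConfig, schedule: DrugSchedule,
                   params: Optional[ModelParameters] = None,
                   seed: int = 0,
                   initial_state: Optional[PopulationState] = None,
                   initial_traits: Optional[ResistanceTraits] = None,
                   record: bool = True) -> Trajectory:
    """Run one Gillespie trial to extinction or the schedule horizon.

    The default initial condition is 50 cells in the 2N+ state with
    v = [0, 0]. Set ``record=False`` to skip the per-event history and
    keep only the summary fields (faster for large ensembles).
    """
    p = scenario.resolve(params)
    state = initial_state if initial_state is not None else PopulationState(50, 0, 0)
    traits = initial_traits if initial_traits is not None else ResistanceTraits()
    horizon = schedule.horizon
    if horizon <= 0:
        raise ConfigError("schedule horizon must be > 0")

    rng = np.random.RandomState(int(seed))
    traj = Trajectory(initial_state=state, initial_traits=traits)
    t = 0.0
    intervals = schedule.intervals
    k = 0

    while True:
        if state.extinct:
            traj.extinct = True
            traj.extinction_time = t
            break
        if t >= horizon:
            break
        while t >= intervals[k].t_end:
            k += 1
        iv = intervals[k]
        doses = iv.doses(p.m)
        boundary = iv.t_end

        ev_rates = compute_event_rates(state, traits, p, scenario=scenario,
                                       doses=doses)
        total = ev_rates.total
        dt = draw_waiting_time(total, rng)
        if t + dt >= boundary:
            # tentative event overshoots the boundary (or the system is
            # quiescent): discard it and restart the clock at the boundary
            t = boundary
            continue
        t = t + dt

        event = select_event(ev_rates, rng)
        traj.n_events += 1
        state = apply_event(state, event, rng=rng, zeta=p.zeta,
                            depoly_to_sensitive=scenario.depoly_to_sensitive)
        if event in ("birth_N", "birth_R"):
            traits = propose_and_resolve_mutation(
                traits, p.sigma1, doses, p, state, rng, scenario, "division")
        elif event == "switch_P_to_R":
            traits = propose_and_resolve_mutation(
                traits, p.sigma2, doses, p, state, rng, scenario,
                "depolyploidization")

        if record:
            traj.times.append(t)
            traj.events.append(event)
            traj.states.append(state)
            traj.traits.append(traits)

    traj.final_time = min(t, horizon)
    traj.final_state = state
    traj.final_traits = traits
    return traj
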