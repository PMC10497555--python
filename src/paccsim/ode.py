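"""Deterministic mean-field reference for the three-state model.

Integrates the ODE system the stochastic rates are read from, piecewise
over the therapy-schedule intervals (propensities are discontinuous at the
boundaries, so the solver is restarted there). Traits are frozen per
integration — the evolutionary dynamics are defined only at the stochastic
level — but a quasi-static trait ramp can be supplied for exploration
(this mode is an extension of the published model, not part of it).

The module serves as a verification oracle: stochastic ensemble means must
match these solutions in the large-population, no-extinction regime, and
the drug-free equilibrium it finds is the pre-therapy operating point of
every experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import (ConfigError, DrugSchedule, ModelParameters,
                     PopulationState, ResistanceTraits, N_DRUGS)
from .rates import per_capita_drug_death
from .scenarios import ScenarioConfig

__all__ = ["OdeSolution", "EquilibriumResult", "rhs", "integrate", "equilibrium"]


@dataclass
class OdeSolution:
    """Mean-field solution on a reporting grid."""

    t: np.ndarray
    N: np.ndarray
    P: np.ndarray
    R: np.ndarray
    scenario: ScenarioConfig
    params: ModelParameters

    @property
    def total(self) -> np.ndarray:
        return self.N + self.P + self.R

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "N": self.N, "P": self.P, "R": self.R})

    def at(self, time: float) -> Tuple[float, float, float]:
        """(N, P, R) linearly interpolated at ``time``."""
        return tuple(float(np.interp(time, self.t, y))
                     for y in (self.N, self.P, self.R))


def rhs(y, traits: ResistanceTraits, params: ModelParameters,
        scenario: ScenarioConfig, doses) -> np.ndarray:
    """Right-hand side d(N,P,R)/dt at state ``y`` under the given doses.

    The mean-field counterpart of the nine stochastic channels; the
    logistic term appears as a net (possibly negative) rate here.
    """
    N, P, R = y
    p = params
    g = p.r * (p.K - (N + P + R)) / p.K
    kill_N = sum(per_capita_drug_death(m, p.lambda_N, p.beta, traits.v[i])
                 for i, m in enumerate(doses))
    lam_R = scenario.lambda_r_eff(p, traits)
    c_R = scenario.c_r_eff(p, traits)
    kill_R = sum(per_capita_drug_death(m, lam_R, p.beta, traits.v[i])
                 for i, m in enumerate(doses))

    eP = scenario.enable_pacc
    eR = scenario.enable_resistant

    dN = g * N - N * kill_N
    dP = 0.0
    dR = 0.0
    if eP:
        dN -= p.gamma * N + p.c_N * N * kill_N
        dP += p.zeta * (p.gamma * N + p.c_N * N * kill_N) - (p.a + p.b) * P
        if scenario.depoly_to_sensitive:
            dN += 2.0 * p.a * P
    if eR:
        dR = (g * R - p.gamma * R - R * kill_R - c_R * R * kill_R
              + 2.0 * p.a * P - p.mu * R)
        dP += p.zeta * (p.gamma * R + c_R * R * kill_R)
        dN += p.mu * R
    return np.array([dN, dP, dR])


def integrate(scenario: ScenarioConfig, schedule: DrugSchedule,
              params: Optional[ModelParameters] = None,
              initial_state: Optional[PopulationState] = None,
              traits: ResistanceTraits = ResistanceTraits(),
              t_span: Optional[Tuple[float, float]] = None,
              rtol: float = 1e-8, atol: float = 1e-8,
              grid_dt: float = 0.5,
              traits_fn: Optional[Callable[[float], ResistanceTraits]] = None,
              ) -> OdeSolution:
    """Adaptive integration of the mean-field system over the schedule.

    The solver restarts at every schedule boundary. ``traits_fn`` (a map
    t -> traits) enables the exploratory quasi-static mode; by default the
    trait vector is fixed for the whole span. Negative excursions beyond
    the tolerance raise; smaller ones are clipped at segment restarts.
    """
    p = scenario.resolve(params)
    y0 = np.array((initial_state or PopulationState(50, 0, 0)).as_tuple(),
                  dtype=float)
    t0, t1 = t_span if t_span is not None else (0.0, schedule.horizon)
    if not 0.0 <= t0 < t1 <= schedule.horizon:
        raise ConfigError("t_span must lie within the schedule")

    ts, ys = [np.array([t0])], [y0.reshape(3, 1)]
    t = t0
    y = y0
    for iv in schedule.intervals:
        if iv.t_end <= t0 or iv.t_start >= t1:
            continue
        seg = (max(t, iv.t_start), min(t1, iv.t_end))
        doses = iv.doses(p.m)

        def f(tt, yy):
            tr = traits_fn(tt) if traits_fn is not None else traits
            return rhs(yy, tr, p, scenario, doses)

        sol = solve_ivp(f, seg, y, method="LSODA", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on segment {seg}: {sol.message}")
        grid = np.arange(seg[0], seg[1], grid_dt)[1:]
        grid = np.append(grid, seg[1])
        yy = sol.sol(grid)
        if yy.min() < -100 * max(atol, 1e-12):
            raise RuntimeError("mean-field solution went significantly negative")
        yy = np.clip(yy, 0.0, None)
        ts.append(grid)
        ys.append(yy)
        t = seg[1]
        y = yy[:, -1]

    tgrid = np.concatenate(ts)
    ygrid = np.concatenate(ys, axis=1)
    return OdeSolution(t=tgrid, N=ygrid[0], P=ygrid[1], R=ygrid[2],
                       scenario=scenario, params=p)


@dataclass
class EquilibriumResult:
    state: PopulationState
    unique: bool


def equilibrium(scenario: ScenarioConfig,
                params: Optional[ModelParameters] = None,
                traits: ResistanceTraits = ResistanceTraits()) -> EquilibriumResult:
    """Drug-free non-trivial equilibrium of the mean-field system.

    Found numerically from several starting points near carrying capacity;
    flagged non-unique if distinct non-negative non-trivial roots are
    found. The trivial extinction fixed point (0,0,0) is excluded.
    """
    p = scenario.resolve(params)
    doses = (0.0,) * N_DRUGS
    # solve the reduced system over the compartments the scenario enables
    active = [0] + ([1] if scenario.enable_pacc else []) \
        + ([2] if scenario.enable_resistant else [])

    def f(x):
        y = np.zeros(3)
        y[active] = x
        return rhs(y, traits, p, scenario, doses)[active]

    guesses = [
        np.array([p.K, 0.05 * p.K, 0.05 * p.K])[active],
        np.array([0.9 * p.K, 0.1 * p.K, 0.01 * p.K])[active],
        np.array([0.5 * p.K, 0.5 * p.K, 0.5 * p.K])[active],
    ]
    roots = []
    for g in guesses:
        sol = root(f, g, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1e-9):
            continue
        y = np.zeros(3)
        y[active] = np.clip(x, 0.0, None)
        if y.sum() < 1e-6:          # trivial extinction root
            continue
        if not any(np.allclose(y, r0, atol=1e-6) for r0 in roots):
            roots.append(y)
    if not roots:
        raise RuntimeError("no non-negative non-trivial equilibrium found")
    y = roots[0]
    return EquilibriumResult(state=PopulationState(*y), unique=len(roots) == 1)
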