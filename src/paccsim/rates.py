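"""Deterministic rate laws of the three-state model.

All nine event-channel propensities are read off the mean-field system

    dN/dt = r N (K-N-P-R)/K - gamma N - sum_i [ N k_N,i + c_N N k_N,i ] + mu R
    dP/dt = zeta gamma (N+R) + zeta sum_i [ c_N N k_N,i + c_R(v) R k_R,i ]
            - a P - b P
    dR/dt = r R (K-N-P-R)/K - gamma R - sum_i [ R k_R,i + c_R(v) R k_R,i ]
            + 2 a P - mu R

with Michaelis-Menten per-capita kill rates k_s,i = m_i / (lambda_s + beta v_i)
(sums run over the drugs active in the current schedule interval).  Both the
stochastic engine and the ODE reference read their rates from this module.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .params import (
    ConfigError,
    EventRates,
    ModelParameters,
    PopulationState,
    ResistanceTraits,
    N_DRUGS,
)
from .scenarios import ScenarioConfig, logistic_saturation

__all__ = [
    "per_capita_drug_death",
    "lambda_R_of_v",
    "c_R_of_v",
    "logistic_birth_rate",
    "compute_event_rates",
    "fitness",
]


def _check_nonneg_finite(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not (isinstance(val, (int, float)) and math.isfinite(val) and val >= 0):
            raise ConfigError(f"{name} must be finite and >= 0, got {val!r}")


def per_capita_drug_death(m: float, lam: float, beta: float, v_i: float) -> float:
    """Per-capita kill rate m / (lam + beta * v_i) for one drug (day^-1).

    Michaelis-Menten in the evolved resistance trait: strictly decreasing
    in v_i whenever the dose m is positive, vanishing as v_i -> inf.
    """
    _check_nonneg_finite(m=m, lam=lam, beta=beta, v_i=v_i)
    denom = lam + beta * v_i
    if denom <= 0:
        raise ConfigError("kill denominator lam + beta*v_i must be > 0")
    return m / denom


def lambda_R_of_v(lambda_R_ceiling: float, traits: ResistanceTraits) -> float:
    """Trait-coupled innate resistance of 2N+(R): ceiling / (1 + exp(-2 sum v))."""
    return logistic_saturation(lambda_R_ceiling, traits)


def c_R_of_v(c_R_ceiling: float, traits: ResistanceTraits) -> float:
    """Trait-coupled facultative PAT scaling of 2N+(R), same logistic form."""
    return logistic_saturation(c_R_ceiling, traits)


def logistic_birth_rate(n_focal: float, state: PopulationState,
                        r: float, K: float) -> float:
    """Birth propensity max(0, r * n_focal * (K - N - P - R) / K).

    The mean-field logistic term is a net rate; the stochastic model
    realizes it as a birth-only channel clamped at zero (no separate
    crowding-death channel), so the propensity is zero at or above
    carrying capacity.
    """
    if K <= 0:
        raise ConfigError("carrying capacity K must be > 0")
    _check_nonneg_finite(n_focal=n_focal, r=r)
    return max(0.0, r * n_focal * (K - state.total) / K)


def _doses_vector(params: ModelParameters, active_drugs,
                  doses: Optional[Sequence[float]]) -> tuple:
    """Per-drug dose vector from an active-drug set (dose = params.m) or explicit doses."""
    if doses is not None:
        if len(doses) != N_DRUGS:
            raise ConfigError(f"doses must have length {N_DRUGS}")
        _check_nonneg_finite(**{f"dose[{i}]": d for i, d in enumerate(doses)})
        return tuple(float(d) for d in doses)
    active = frozenset(int(d) for d in active_drugs or ())
    for d in active:
        if not 0 <= d < N_DRUGS:
            raise ConfigError(f"unknown drug id {d}")
    return tuple(params.m if d in active else 0.0 for d in range(N_DRUGS))


def compute_event_rates(state: PopulationState, traits: ResistanceTraits,
                        params: ModelParameters, active_drugs=(),
                        scenario: Optional[ScenarioConfig] = None,
                        doses: Optional[Sequence[float]] = None) -> EventRates:
    """The nine event propensities at the given state, traits and active drugs.

    Parameters
    ----------
    active_drugs : collection of int
        Drug ids active in the current schedule interval; each contributes
        dose ``params.m``. Alternatively pass ``doses`` explicitly (one
        entry per drug; zero for inactive drugs).
    scenario
        Determines which compartments exist and whether lambda_R / c_R are
        constants or trait-coupled. ``None`` means the full model with
        constant lambda_R, c_R.

    Channels of disabled compartments are identically zero; with no active
    drug all kill and facultative terms vanish exactly.
    """
    if scenario is None:
        scenario = ScenarioConfig(name="full")
    mvec = _doses_vector(params, active_drugs, doses)

    N, P, R = state.N, state.P, state.R
    if not scenario.enable_pacc and P > 0:
        raise ConfigError(f"scenario {scenario.name!r} disables the PACC state but P={P}")
    if not scenario.enable_resistant and R > 0:
        raise ConfigError(f"scenario {scenario.name!r} disables the 2N+(R) state but R={R}")

    kill_N = sum(per_capita_drug_death(m, params.lambda_N, params.beta, traits.v[i])
                 for i, m in enumerate(mvec))
    lam_R = scenario.lambda_r_eff(params, traits)
    c_R = scenario.c_r_eff(params, traits)
    kill_R = sum(per_capita_drug_death(m, lam_R, params.beta, traits.v[i])
                 for i, m in enumerate(mvec)) if scenario.enable_resistant else 0.0

    birth_N = logistic_birth_rate(N, state, params.r, params.K)
    birth_R = logistic_birth_rate(R, state, params.r, params.K) \
        if scenario.enable_resistant else 0.0
    switch_N_to_P = (params.gamma * N + params.c_N * N * kill_N) \
        if scenario.enable_pacc else 0.0
    switch_R_to_P = (params.gamma * R + c_R * R * kill_R) \
        if scenario.enable_resistant else 0.0

    return EventRates(
        birth_N=birth_N,
        birth_R=birth_R,
        death_N=N * kill_N,
        death_P=params.b * P if scenario.enable_pacc else 0.0,
        death_R=R * kill_R,
        switch_N_to_P=switch_N_to_P,
        switch_P_to_R=params.a * P if scenario.enable_pacc else 0.0,
        switch_R_to_P=switch_R_to_P,
        switch_R_to_N=params.mu * R if scenario.enable_resistant else 0.0,
    )


def fitness(state: PopulationState, traits: ResistanceTraits,
            params: ModelParameters, active_drugs=(),
            scenario: Optional[ScenarioConfig] = None,
            compartment: str = "N",
            doses: Optional[Sequence[float]] = None) -> float:
    """Instantaneous per-capita net growth rate of a proliferative state.

    Used to compare a resident trait vector against a proposed mutant
    (invasion-implies-substitution): the logistic term, obligate PAT loss,
    drug kill and facultative PAT loss of the focal state, evaluated at
    the current population sizes and doses. Only the sign of
    mutant - resident matters for acceptance.
    """
    if scenario is None:
        scenario = ScenarioConfig(name="full")
    if compartment not in ("N", "R"):
        raise ConfigError("fitness is defined for the proliferative states 'N' and 'R'")
    mvec = _doses_vector(params, active_drugs, doses)

    growth = params.r * (params.K - state.total) / params.K
    gamma = params.gamma if scenario.enable_pacc else 0.0
    if compartment == "N":
        kill = sum(per_capita_drug_death(m, params.lambda_N, params.beta, traits.v[i])
                   for i, m in enumerate(mvec))
        facultative = params.c_N * kill if scenario.enable_pacc else 0.0
    else:
        lam_R = scenario.lambda_r_eff(params, traits)
        c_R = scenario.c_r_eff(params, traits)
        kill = sum(per_capita_drug_death(m, lam_R, params.beta, traits.v[i])
                   for i, m in enumerate(mvec))
        facultative = c_R * kill
    return growth - gamma - kill - facultative
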