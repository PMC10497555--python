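"""Model variants (cross-resistance hypotheses) and therapy schedules.

Five scenarios are studied:

``single_state``
    Control without any PACC biology: the population lives in the 2N+
    state only and can adapt only by mutation at division.
``pacc_no_R``
    Control with a PACC refuge but no post-PACC memory: the 2N+(R) state
    is removed and depolyploidization returns two ordinary 2N+ cells.
``pacc_memory``
    Cells that have passed through the PACC state re-enter it faster:
    the facultative transition scaling of 2N+(R) cells, c_R(v), rises
    logistically with accumulated resistance, while their innate
    resistance stays at the 2N+ baseline (lambda_R = lambda_N, mu = 0).
``innate_resistance``
    Post-PACC cells gain drug-agnostic innate resistance: lambda_R(v)
    rises logistically toward its ceiling with accumulated resistance,
    while c_R = c_N and mu = 0.
``temporary_innate_resistance``
    As ``innate_resistance`` but the gain is transient: 2N+(R) cells
    resensitize back to 2N+ at rate mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Optional, Tuple

from .params import (
    ConfigError,
    DrugSchedule,
    Interval,
    ModelParameters,
    ResistanceTraits,
)

__all__ = [
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "make_scenario",
    "make_schedule",
    "logistic_saturation",
]


SCENARIO_NAMES: Tuple[str, ...] = (
    "single_state",
    "pacc_no_R",
    "pacc_memory",
    "innate_resistance",
    "temporary_innate_resistance",
)


def logistic_saturation(ceiling: float, traits: ResistanceTraits) -> float:
    """ceiling / (1 + exp(-2 * sum_i v_i)).

    The trait-coupling used by both lambda_R(v) and c_R(v): half the
    ceiling at v = 0, saturating at the ceiling as resistance accumulates.
    """
    import math

    if ceiling < 0:
        raise ConfigError("saturation ceiling must be >= 0")
    return ceiling / (1.0 + math.exp(-2.0 * traits.total))


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully resolved description of one model variant.

    ``overrides`` are parameter replacements layered on top of the model
    defaults (e.g. a non-default dose m or mutational breadth sigma2).
    ``pinned_mu`` is the scenario-mandated resensitization rate; an
    explicit ``mu`` override takes precedence so that e.g. the
    temporary-innate-resistance scenario at mu=0 reduces exactly to the
    innate-resistance scenario.
    """

    name: str
    enable_pacc: bool = True
    enable_resistant: bool = True
    depoly_to_sensitive: bool = False
    lambda_r_vdep: bool = False
    lambda_r_equals_n: bool = False
    c_r_vdep: bool = False
    c_r_equals_n: bool = False
    pinned_mu: Optional[float] = None
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "overrides", MappingProxyType(dict(self.overrides)))
        if self.enable_resistant and not self.enable_pacc:
            raise ConfigError(
                "the 2N+(R) state is only reachable through the PACC state; "
                "cannot enable R with P disabled")
        if self.depoly_to_sensitive and self.enable_resistant:
            raise ConfigError("depolyploidization routes to 2N+ only when the "
                              "2N+(R) state is disabled")

    def resolve(self, params: Optional[ModelParameters] = None) -> ModelParameters:
        """Effective parameters: defaults <- overrides <- scenario mu pin."""
        base = params if params is not None else ModelParameters()
        resolved = base.with_overrides(self.overrides)
        if self.pinned_mu is not None and "mu" not in self.overrides:
            resolved = replace(resolved, mu=self.pinned_mu)
        return resolved

    # -- trait-dependent effective rate constants ------------------------

    def lambda_r_eff(self, params: ModelParameters, traits: ResistanceTraits) -> float:
        """Innate resistance of the 2N+(R) state, possibly trait-coupled."""
        base = params.lambda_N if self.lambda_r_equals_n else params.lambda_R
        return logistic_saturation(base, traits) if self.lambda_r_vdep else base

    def c_r_eff(self, params: ModelParameters, traits: ResistanceTraits) -> float:
        """Facultative PAT scaling of the 2N+(R) state, possibly trait-coupled."""
        base = params.c_N if self.c_r_equals_n else params.c_R
        return logistic_saturation(base, traits) if self.c_r_vdep else base

    def with_override(self, key: str, value: float) -> "ScenarioConfig":
        ModelParameters().with_overrides({key: value})  # validates the key
        merged = dict(self.overrides)
        merged[key] = float(value)
        return replace(self, overrides=merged)

    def to_dict(self) -> dict:
        return {"scenario": self.name, **{k: float(v) for k, v in self.overrides.items()}}


_SCENARIO_FLAGS = {
    "single_state": dict(enable_pacc=False, enable_resistant=False),
    "pacc_no_R": dict(enable_pacc=True, enable_resistant=False,
                      depoly_to_sensitive=True),
    "pacc_memory": dict(lambda_r_equals_n=True, c_r_vdep=True, pinned_mu=0.0),
    "innate_resistance": dict(lambda_r_vdep=True, c_r_equals_n=True, pinned_mu=0.0),
    "temporary_innate_resistance": dict(lambda_r_vdep=True, c_r_equals_n=True),
}


def make_scenario(name: str, **overrides: float) -> ScenarioConfig:
    """Build one of the named model variants, optionally overriding parameters.

    Parameters
    ----------
    name : str
        One of :data:`SCENARIO_NAMES`.
    **overrides
        Replacements for model parameters (``m``, ``sigma2``, ``c_R``,
        ``lambda_R``, ``mu``, ...). Unknown keys raise :class:`ConfigError`.
    """
    if name not in _SCENARIO_FLAGS:
        raise ConfigError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    ModelParameters().with_overrides(overrides)  # validate keys/values early
    return ScenarioConfig(name=name, overrides=dict(overrides), **_SCENARIO_FLAGS[name])


def make_schedule(same_drug: bool = True, horizon: float = 900.0,
                  dose: Optional[float] = None) -> DrugSchedule:
    """The two-challenge therapy design.

    No therapy on [0, 100); drug 1 on [100, 400); holiday on [400, 500);
    drug 1 (``same_drug``) or drug 2 on [500, 800); no therapy to the
    horizon. Drug ids are 0-based internally (drug 1 -> id 0).
    """
    if horizon < 800:
        raise ConfigError("canonical schedule needs horizon >= 800")
    second = frozenset({0}) if same_drug else frozenset({1})
    return DrugSchedule(intervals=(
        Interval(0.0, 100.0),
        Interval(100.0, 400.0, frozenset({0}), dose),
        Interval(400.0, 500.0),
        Interval(500.0, 800.0, second, dose),
        Interval(800.0, horizon),
    ))
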