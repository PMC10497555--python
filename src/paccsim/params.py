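"""Core domain types for the state-structured PACC model.

The model tracks a cancer cell population structured into three states:

* ``N`` — proliferative, therapy-susceptible aneuploid cells (2N+),
* ``P`` — non-proliferative, therapy-refractory polyaneuploid cells (PACC),
* ``R`` — proliferative cells that have passed through the PACC state
  (2N+(R)), which may carry elevated innate resistance or a "memory" of
  the polyaneuploid transition depending on the scenario.

Populations are counted in units of 10^7 cells so that the carrying
capacity K=100 corresponds to 10^9 literal cells while event-level
simulation stays tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ModelParameters",
    "PopulationState",
    "ResistanceTraits",
    "Interval",
    "DrugSchedule",
    "EventRates",
    "EVENT_ORDER",
    "ConfigError",
    "N_DRUGS",
]

#: Number of independent therapies in the two-drug rechallenge design.
N_DRUGS = 2


class ConfigError(ValueError):
    """Invalid model/scenario/schedule configuration."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants and evolutionary parameters of the model.

    Defaults are the baseline simulation values.

    Parameters
    ----------
    r : float
        Intrinsic growth rate of proliferative states (day^-1).
    K : float
        Carrying capacity (units of 10^7 cells); all three states inhibit
        growth equally.
    gamma : float
        Obligate polyaneuploid-transition (PAT) rate into the PACC state
        (day^-1), present even without therapy.
    m : float
        Drug dosage (day^-1), applied per active drug.
    lambda_N : float
        Innate resistance of 2N+ cells (dimensionless Michaelis-Menten
        half-saturation offset).
    lambda_R : float
        Innate resistance ceiling of 2N+(R) cells.
    beta : float
        Efficacy of the evolved resistance trait in the kill denominator.
    c_N : float
        Facultative (therapy-induced) PAT scaling for 2N+ cells (day^-1
        per unit per-capita kill rate).
    c_R : float
        Facultative PAT scaling ceiling for 2N+(R) cells.
    a : float
        Depolyploidization rate, PACC -> 2N+(R) (day^-1); each event
        yields two proliferative daughters.
    b : float
        Background PACC death rate (day^-1).
    mu : float
        Resensitization rate 2N+(R) -> 2N+ (day^-1); active only under the
        temporary-innate-resistance hypothesis.
    zeta : float
        Probability that a PAT succeeds (otherwise mitotic catastrophe
        kills the transitioning cell).
    phi : float
        Mutation probability per division / depolyploidization.
    sigma1 : float
        Mutational breadth (Gaussian SD) on 2N+/2N+(R) division.
    sigma2 : float
        Mutational breadth on PACC depolyploidization; larger than sigma1
        reflects the elevated genomic content of the PACC state.
    """

    r: float = 0.6
    K: float = 100.0
    gamma: float = 0.02
    m: float = 0.7
    lambda_N: float = 1.0
    lambda_R: float = 2.0
    beta: float = 1.0
    c_N: float = 0.4
    c_R: float = 0.8
    a: float = 0.2
    b: float = 0.01
    mu: float = 0.2
    zeta: float = 0.7
    phi: float = 0.05
    sigma1: float = 0.01
    sigma2: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            _require(isinstance(val, (int, float)) and math.isfinite(val),
                     f"parameter {f.name!r} must be a finite number, got {val!r}")
            _require(val >= 0, f"parameter {f.name!r} must be >= 0, got {val}")
        _require(self.K > 0, "carrying capacity K must be > 0")
        _require(0.0 <= self.zeta <= 1.0, "zeta is a probability in [0, 1]")
        _require(0.0 <= self.phi <= 1.0, "phi is a probability in [0, 1]")
        _require(self.sigma1 > 0 and self.sigma2 > 0,
                 "mutational breadths sigma1, sigma2 must be > 0")

    # -- flat key/value round trip -------------------------------------

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with the given fields replaced (unknown keys error)."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown parameter overrides: {sorted(unknown)}")
        return replace(self, **{k: float(v) for k, v in overrides.items()})

    @staticmethod
    def field_names() -> Tuple[str, ...]:
        return tuple(f.name for f in fields(ModelParameters))


@dataclass(frozen=True)
class PopulationState:
    """Counts of cells in the 2N+ (N), PACC (P) and 2N+(R) (R) states.

    Counts are in units of 10^7 cells: integer-valued in the stochastic
    engine, non-negative reals in the deterministic mean-field mode.
    """

    N: float
    P: float = 0.0
    R: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N", "P", "R"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0,
                     f"compartment {name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.N + self.P + self.R

    @property
    def extinct(self) -> bool:
        """Extinction (total count zero) is absorbing."""
        return self.total == 0

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.N, self.P, self.R)


@dataclass(frozen=True)
class ResistanceTraits:
    """Population-level resistance strategy vector v = [v1, v2].

    ``v[i]`` is the evolved (heritable) resistance to drug ``i``; it is a
    resident trait of the whole population, not a per-cell attribute, and
    under the invasion-implies-substitution acceptance rule it is
    non-decreasing along any trajectory.
    """

    v: Tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", tuple(float(x) for x in self.v))
        _require(len(self.v) == N_DRUGS, f"expected {N_DRUGS} trait entries")
        for i, x in enumerate(self.v):
            _require(math.isfinite(x) and x >= 0.0,
                     f"trait v[{i}] must be finite and >= 0, got {x}")

    @property
    def total(self) -> float:
        return sum(self.v)

    def bumped(self, i: int, delta: float) -> "ResistanceTraits":
        """Traits with v[i] incremented by ``delta`` (result must stay >= 0)."""
        new = list(self.v)
        new[i] += delta
        return ResistanceTraits(tuple(new))


@dataclass(frozen=True)
class Interval:
    """One schedule interval: [t_start, t_end) with a set of active drugs.

    ``dose`` overrides the model dose m for this interval; ``None`` means
    use the model parameter.
    """

    t_start: float
    t_end: float
    drugs: frozenset = frozenset()
    dose: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(int(d) for d in self.drugs))
        _require(self.t_start < self.t_end, "interval must have t_start < t_end")
        for d in self.drugs:
            _require(0 <= d < N_DRUGS, f"unknown drug id {d}")
        if self.dose is not None:
            _require(self.dose >= 0, "dose must be >= 0")

    def doses(self, default_m: float) -> Tuple[float, ...]:
        """Per-drug dose vector over this interval (0 for inactive drugs)."""
        m = default_m if self.dose is None else self.dose
        return tuple(m if d in self.drugs else 0.0 for d in range(N_DRUGS))


@dataclass(frozen=True)
class DrugSchedule:
    """Ordered, contiguous, non-overlapping therapy intervals from 0 to the horizon."""

    intervals: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        _require(len(self.intervals) > 0, "schedule must have at least one interval")
        _require(self.intervals[0].t_start == 0.0, "schedule must start at t=0")
        for prev, nxt in zip(self.intervals, self.intervals[1:]):
            _require(prev.t_end == nxt.t_start,
                     "intervals must be contiguous and non-overlapping")

    @property
    def horizon(self) -> float:
        return self.intervals[-1].t_end

    def interval_at(self, t: float) -> Interval:
        """The interval containing time t (right-open; horizon maps to the last one)."""
        _require(0.0 <= t <= self.horizon, f"time {t} outside schedule")
        for iv in self.intervals:
            if t < iv.t_end:
                return iv
        return self.intervals[-1]

    def boundaries(self) -> Tuple[float, ...]:
        return tuple(iv.t_end for iv in self.intervals)

    def dose_arrays(self, default_m: float):
        """(end_times, dose_drug1, dose_drug2) arrays for the event loop."""
        import numpy as np

        ends = np.array([iv.t_end for iv in self.intervals], dtype=np.float64)
        doses = np.array([iv.doses(default_m) for iv in self.intervals],
                         dtype=np.float64)
        return ends, doses[:, 0], doses[:, 1]


#: Canonical ordering of the nine event channels; the stochastic engine's
#: selection draw walks this order, so it is part of the reproducibility
#: contract.
EVENT_ORDER: Tuple[str, ...] = (
    "birth_N",
    "birth_R",
    "death_N",
    "death_P",
    "death_R",
    "switch_N_to_P",
    "switch_P_to_R",
    "switch_R_to_P",
    "switch_R_to_N",
)


@dataclass(frozen=True)
class EventRates:
    """The nine event-channel propensities (day^-1) of the birth-death-switching process."""

    birth_N: float = 0.0
    birth_R: float = 0.0
    death_N: float = 0.0
    death_P: float = 0.0
    death_R: float = 0.0
    switch_N_to_P: float = 0.0
    switch_P_to_R: float = 0.0
    switch_R_to_P: float = 0.0
    switch_R_to_N: float = 0.0

    def __post_init__(self) -> None:
        for name in EVENT_ORDER:
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0.0,
                     f"rate {name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in EVENT_ORDER)

    def as_tuple(self) -> Tuple[float, ...]:
        return tuple(getattr(self, name) for name in EVENT_ORDER)

    def __iter__(self) -> Iterator[Tuple[str, float]]:
        return iter((name, getattr(self, name)) for name in EVENT_ORDER)
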