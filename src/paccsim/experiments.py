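"""Extinction-probability experiments: replicate sets, sweeps, summaries.

The headline experiment runs ``n_sets`` x ``n_trials`` independent
stochastic trials of a scenario under a therapy schedule and reports the
mean and across-set standard deviation of the per-set extinction
percentage. One-dimensional parameter sweeps reuse the same per-trial seed
streams for every value, so comparisons along the sweep (and between
schedule arms run at the same base seed) are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import ConfigError, DrugSchedule, ModelParameters, PopulationState, ResistanceTraits
from .engine import RngPolicy, simulate_trial
from .scenarios import ScenarioConfig
from . import _kernel

__all__ = ["ExperimentResult", "SweepResult", "run_replicates", "sweep",
           "extinction_summary"]


@dataclass
class ExperimentResult:
    """Outcome of one scenario x schedule replicate experiment."""

    scenario: ScenarioConfig
    schedule: DrugSchedule
    params: ModelParameters          # resolved (scenario overrides applied)
    n_sets: int
    n_trials: int
    base_seed: int
    trials: pd.DataFrame             # set, trial, seed, extinct, extinction_time, N,P,R,v1,v2

    @property
    def per_set_extinctions(self) -> np.ndarray:
        counts = self.trials.groupby("set")["extinct"].sum()
        return counts.reindex(range(self.n_sets), fill_value=0).to_numpy(dtype=int)

    @property
    def per_set_percentages(self) -> np.ndarray:
        return 100.0 * self.per_set_extinctions / self.n_trials

    @property
    def mean_extinction_pct(self) -> float:
        return float(np.mean(self.per_set_percentages))

    @property
    def sd_extinction_pct(self) -> float:
        """Sample (n-1) SD of the per-set extinction percentages."""
        pct = self.per_set_percentages
        return float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0

    def extinction_ci(self, confidence: float = 0.99) -> Tuple[float, float]:
        """Clopper-Pearson CI (in %) on the pooled extinction probability."""
        k = int(self.trials["extinct"].sum())
        n = len(self.trials)
        alpha = 1.0 - confidence
        lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        return 100.0 * lo, 100.0 * hi

    def summary_row(self) -> dict:
        lo, hi = self.extinction_ci()
        return {
            "scenario": self.scenario.name,
            "mean_extinction_pct": self.mean_extinction_pct,
            "sd_extinction_pct": self.sd_extinction_pct,
            "ci99_lo_pct": lo,
            "ci99_hi_pct": hi,
            "n_sets": self.n_sets,
            "n_trials": self.n_trials,
            "base_seed": self.base_seed,
        }


def extinction_summary(result: ExperimentResult) -> Tuple[float, float]:
    """(mean %, across-set sample SD %) of the per-set extinction percentages."""
    return result.mean_extinction_pct, result.sd_extinction_pct


def _kernel_inputs(scenario: ScenarioConfig, schedule: DrugSchedule,
                   params: ModelParameters, initial_state: PopulationState,
                   initial_traits: ResistanceTraits):
    ends, dose1, dose2 = schedule.dose_arrays(params.m)
    lamR_base = params.lambda_N if scenario.lambda_r_equals_n else params.lambda_R
    cR_base = params.c_N if scenario.c_r_equals_n else params.c_R
    return dict(
        n0=int(initial_state.N), p0=int(initial_state.P), r0=int(initial_state.R),
        v10=float(initial_traits.v[0]), v20=float(initial_traits.v[1]),
        ends=ends, dose1=dose1, dose2=dose2,
        r=params.r, K=params.K, gamma=params.gamma, lamN=params.lambda_N,
        lamR_base=lamR_base, beta=params.beta, cN=params.c_N, cR_base=cR_base,
        a=params.a, b=params.b, mu=params.mu, zeta=params.zeta,
        phi=params.phi, s1=params.sigma1, s2=params.sigma2,
        enable_P=scenario.enable_pacc, enable_R=scenario.enable_resistant,
        depoly_to_N=scenario.depoly_to_sensitive,
        lamR_vdep=scenario.lambda_r_vdep, cR_vdep=scenario.c_r_vdep,
    )


def run_replicates(scenario: ScenarioConfig, schedule: DrugSchedule,
                   params: Optional[ModelParameters] = None,
                   n_sets: int = 10, n_trials: int = 100,
                   base_seed: int = 0,
                   initial_state: Optional[PopulationState] = None,
                   initial_traits: Optional[ResistanceTraits] = None,
                   engine: str = "compiled") -> ExperimentResult:
    """Run ``n_sets`` x ``n_trials`` independent trials of a scenario.

    ``engine`` selects the compiled numba kernel (default) or the
    pure-Python reference engine (``"python"``); both produce identical
    trajectories for a given seed policy.
    """
    if n_sets < 1 or n_trials < 1:
        raise ConfigError("n_sets and n_trials must be >= 1")
    if engine not in ("compiled", "python"):
        raise ConfigError(f"unknown engine {engine!r}")
    p = scenario.resolve(params)
    init = initial_state if initial_state is not None else PopulationState(50, 0, 0)
    traits0 = initial_traits if initial_traits is not None else ResistanceTraits()
    seeds = RngPolicy(base_seed).seed_matrix(n_sets, n_trials)

    if engine == "compiled":
        kw = _kernel_inputs(scenario, schedule, p, init, traits0)
        out = _kernel.simulate_batch(seeds.ravel(), **kw)
        extinct, ext_time, Nf, Pf, Rf, v1f, v2f, nev, tf = out
        trials = pd.DataFrame({
            "set": np.repeat(np.arange(n_sets), n_trials),
            "trial": np.tile(np.arange(n_trials), n_sets),
            "seed": seeds.ravel(),
            "extinct": extinct,
            "extinction_time": ext_time,
            "N": Nf, "P": Pf, "R": Rf, "v1": v1f, "v2": v2f,
            "n_events": nev, "final_time": tf,
        })
    else:
        rows = []
        for s in range(n_sets):
            for tr in range(n_trials):
                traj = simulate_trial(scenario, schedule, p, seed=seeds[s, tr],
                                      initial_state=init, initial_traits=traits0,
                                      record=False)
                rows.append({"set": s, "trial": tr, "seed": seeds[s, tr],
                             **{k: v for k, v in traj.summary().items()
                                if k != "final_time"},
                             "final_time": traj.final_time})
        trials = pd.DataFrame(rows)
        trials["extinction_time"] = trials["extinction_time"].astype(float)

    return ExperimentResult(scenario=scenario, schedule=schedule, params=p,
                            n_sets=n_sets, n_trials=n_trials,
                            base_seed=base_seed, trials=trials)


@dataclass
class SweepResult:
    """One-dimensional parameter sweep: one ExperimentResult per grid value."""

    parameter: str
    values: List[float]
    results: List[ExperimentResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, res in zip(self.values, self.results):
            rows.append({"parameter": self.parameter, "value": v,
                         **res.summary_row()})
        return pd.DataFrame(rows)


#: parameters the sweep interface exposes (all plain rate constants)
SWEEPABLE = ("c_R", "lambda_R", "mu", "m", "sigma2", "sigma1")


def sweep(scenario: ScenarioConfig, schedule: DrugSchedule,
          params: Optional[ModelParameters], parameter: str,
          values: Sequence[float], n_sets: int = 10, n_trials: int = 100,
          base_seed: int = 0, engine: str = "compiled") -> SweepResult:
    """Replicate experiment at each value of one parameter.

    The same base seed (hence the same per-trial streams) is used for every
    value, pairing the comparisons along the grid.
    """
    if parameter not in SWEEPABLE:
        raise ConfigError(f"unknown sweep parameter {parameter!r}; "
                          f"expected one of {SWEEPABLE}")
    results = []
    for val in values:
        sc = scenario.with_override(parameter, float(val))
        results.append(run_replicates(sc, schedule, params, n_sets=n_sets,
                                      n_trials=n_trials, base_seed=base_seed,
                                      engine=engine))
    return SweepResult(parameter=parameter, values=[float(v) for v in values],
                       results=results)
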