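"""Flat key/value run configurations and named presets.

A run configuration is a flat YAML mapping of scalars: the scenario name,
the schedule arm, replication counts, seed, horizon, and any model
parameter overrides. Unknown keys are an error. Presets mirror the
published experiments one-to-one.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .params import ConfigError, ModelParameters
from .scenarios import ScenarioConfig, make_scenario, make_schedule

__all__ = ["RunConfig", "PRESETS", "load_config", "save_config", "preset_config"]

_RUN_KEYS = ("scenario", "schedule", "horizon", "n_sets", "n_trials", "seed")


class RunConfig(dict):
    """Validated flat run configuration (a plain dict with helpers)."""

    def __init__(self, mapping: Mapping):
        known = set(_RUN_KEYS) | set(ModelParameters.field_names())
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "scenario" not in mapping:
            raise ConfigError("configuration must name a scenario")
        merged = {"schedule": "same", "horizon": 900.0,
                  "n_sets": 10, "n_trials": 100, "seed": 0, **mapping}
        if merged["schedule"] not in ("same", "different"):
            raise ConfigError("schedule must be 'same' or 'different'")
        super().__init__(merged)

    @property
    def overrides(self) -> dict:
        return {k: v for k, v in self.items()
                if k in ModelParameters.field_names()}

    def scenario(self) -> ScenarioConfig:
        return make_scenario(self["scenario"], **self.overrides)

    def schedule(self):
        return make_schedule(same_drug=self["schedule"] == "same",
                             horizon=float(self["horizon"]))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")
    return RunConfig(data)


def save_config(cfg: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=True))


def _p(scenario, schedule, **over):
    return {"scenario": scenario, "schedule": schedule, **over}


#: One preset per published experiment arm.
PRESETS = {
    "single-state-low-dose-same": _p("single_state", "same", m=0.5),
    "single-state-low-dose-different": _p("single_state", "different", m=0.5),
    "single-state-high-dose-same": _p("single_state", "same", m=0.7),
    "single-state-high-dose-different": _p("single_state", "different", m=0.7),
    "pacc-low-breadth-same": _p("pacc_no_R", "same", sigma2=0.005),
    "pacc-low-breadth-different": _p("pacc_no_R", "different", sigma2=0.005),
    "pacc-medium-breadth-same": _p("pacc_no_R", "same", sigma2=0.01),
    "pacc-medium-breadth-different": _p("pacc_no_R", "different", sigma2=0.01),
    "pacc-high-breadth-same": _p("pacc_no_R", "same", sigma2=0.05),
    "pacc-high-breadth-different": _p("pacc_no_R", "different", sigma2=0.05),
    "pacc-memory-same": _p("pacc_memory", "same"),
    "pacc-memory-different": _p("pacc_memory", "different"),
    "innate-resistance-same": _p("innate_resistance", "same"),
    "innate-resistance-different": _p("innate_resistance", "different"),
    "temporary-innate-resistance-same": _p("temporary_innate_resistance", "same"),
    "temporary-innate-resistance-different": _p("temporary_innate_resistance", "different"),
}


def preset_config(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return RunConfig(PRESETS[name])
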