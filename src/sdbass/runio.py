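"""Run configuration, trajectory export, and reproducible replay.

A run is described by a scenario name plus optional constant/lookup/sim
overrides, supplied programmatically, via a YAML config file, or via CLI
flags. Every run writes a JSON metadata sidecar holding all *effective*
parameters; `replay` rebuilds and re-runs a simulation from that sidecar
alone, reproducing the trajectory bit-for-bit (the model is deterministic).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .engine import (
    ConfigurationError,
    LookupTable,
    RampInput,
    SimConfig,
    StepInput,
    Trajectory,
    integrate,
)
from .model import DEFAULT_CONSTANTS, ModelConstants, build_base_model
from .scenarios import apply_scenario, get_scenario

__all__ = [
    "RunConfig",
    "load_run_config",
    "run",
    "export_trajectory",
    "write_metadata",
    "replay",
    "serialize_override",
    "deserialize_override",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run.

    `seed` is accepted for interface uniformity but unused: the model has no
    stochastic element.
    """

    scenario: str = "base"
    constants: dict = field(default_factory=dict)      # ModelConstants field overrides
    element_overrides: dict = field(default_factory=dict)  # constant/lookup overrides
    sim: dict = field(default_factory=dict)            # SimConfig field overrides
    seed: int | None = None

    def model_constants(self) -> ModelConstants:
        unknown = set(self.constants) - {f.name for f in dataclasses.fields(ModelConstants)}
        if unknown:
            raise ConfigurationError(f"unknown constants override(s): {sorted(unknown)}")
        return dataclasses.replace(DEFAULT_CONSTANTS, **self.constants)

    def sim_config(self) -> SimConfig:
        unknown = set(self.sim) - {f.name for f in dataclasses.fields(SimConfig)}
        if unknown:
            raise ConfigurationError(f"unknown sim override(s): {sorted(unknown)}")
        return dataclasses.replace(SimConfig(), **self.sim)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file (all keys optional)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.element_overrides = {
        name: deserialize_override(value) if isinstance(value, dict) else value
        for name, value in cfg.element_overrides.items()
    }
    return cfg


def run(config: RunConfig) -> Trajectory:
    """Build the scenario model, apply any extra overrides, and integrate."""
    model = apply_scenario(build_base_model(config.model_constants()),
                           get_scenario(config.scenario))
    for element, value in config.element_overrides.items():
        if isinstance(value, LookupTable):
            if element not in model.lookups:
                raise ConfigurationError(f"unknown lookup override {element!r}")
            model.lookups[element] = value
        else:
            if element not in model.constants:
                raise ConfigurationError(f"unknown constant override {element!r}")
            model.constants[element] = value
    return integrate(model, config.sim_config())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def serialize_override(value) -> object:
    if isinstance(value, StepInput):
        return {"type": "step", "base": value.base, "height": value.height,
                "start": value.start}
    if isinstance(value, RampInput):
        return {"type": "ramp", "start_value": value.start_value,
                "end_value": value.end_value, "start_year": value.start_year,
                "end_year": value.end_year}
    if isinstance(value, LookupTable):
        return {"type": "lookup", "points": [list(p) for p in value.points]}
    return float(value)


def deserialize_override(value):
    if not isinstance(value, dict):
        return float(value)
    kind = value.get("type")
    if kind == "step":
        return StepInput(value["base"], value["height"], value["start"])
    if kind == "ramp":
        return RampInput(value["start_value"], value["end_value"],
                         value["start_year"], value["end_year"])
    if kind == "lookup":
        return LookupTable(tuple(tuple(p) for p in value["points"]))
    raise ConfigurationError(f"unknown override type {kind!r}")


def export_trajectory(trajectory: Trajectory, path: str | Path,
                      yearly: bool = True, fmt: str = "csv") -> Path:
    """Write the trajectory as a tidy table (one row per output year)."""
    path = Path(path)
    frame = trajectory.yearly() if yearly else trajectory.data
    if fmt == "csv":
        frame.to_csv(path)
    elif fmt == "json":
        frame.reset_index().to_json(path, orient="records", indent=1)
    else:
        raise ConfigurationError(f"unknown output format {fmt!r}")
    return path


def write_metadata(config: RunConfig, path: str | Path) -> Path:
    """Record all effective parameters of a run as a JSON sidecar."""
    scenario = get_scenario(config.scenario)
    effective_constants = dataclasses.asdict(config.model_constants())
    payload = {
        "package": "sdbass",
        "version": __version__,
        "scenario": config.scenario,
        "scenario_overrides": {k: serialize_override(v)
                               for k, v in scenario.overrides.items()},
        "constants": effective_constants,
        "element_overrides": {k: serialize_override(v)
                              for k, v in config.element_overrides.items()},
        "sim": dataclasses.asdict(config.sim_config()),
        "seed": config.seed,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def replay(metadata_path: str | Path) -> Trajectory:
    """Re-run a simulation from its metadata sidecar (bit-for-bit identical)."""
    meta = json.loads(Path(metadata_path).read_text())
    constants = dict(meta["constants"])
    constants.pop("m", None)
    cfg = RunConfig(
        scenario=meta["scenario"],
        constants=constants,
        element_overrides={k: deserialize_override(v)
                           for k, v in meta.get("element_overrides", {}).items()},
        sim=meta["sim"],
        seed=meta.get("seed"),
    )
    return run(cfg)
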