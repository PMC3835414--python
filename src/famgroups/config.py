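"""Scenario configuration: YAML parsing, validation, provenance.

A scenario file has up to three top-level blocks::

    model:        # any ModelParams field, incl. nested hazard/production/cost
      beta: 100
      sigma_nu: 10
    experiment:
      preset: sweep-beta        # or: run, sweep-gamma, noise-contrast,
                                #     init-study, robustness
      n_runs: 10
      horizon: 2000
      seed_base: 0
    output:
      directory: out
      event_log: false

Unknown keys anywhere are errors (reported with their key path).  The fully
resolved configuration is echoed into a provenance file next to every output
so a run can be reproduced exactly from its artifacts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .params import ConfigError, ModelParams, _from_mapping

__all__ = ["ScenarioConfig", "ExperimentSpec", "OutputSpec", "load_config", "write_provenance"]

_PRESETS = ("run", "sweep-beta", "sweep-gamma", "noise-contrast", "init-study", "robustness")


@dataclass
class ExperimentSpec:
    preset: str = "run"
    n_runs: int = 10
    horizon: int = 2000
    seed_base: int = 0

    def validate(self) -> None:
        if self.preset not in _PRESETS:
            raise ConfigError(f"experiment.preset must be one of {_PRESETS}")
        if self.n_runs < 1:
            raise ConfigError("experiment.n_runs must be >= 1")
        if self.horizon < 1:
            raise ConfigError("experiment.horizon must be >= 1")


@dataclass
class OutputSpec:
    directory: str = "out"
    event_log: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError("output.log_level must be a standard level name")


@dataclass
class ScenarioConfig:
    model: ModelParams = field(default_factory=ModelParams)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    output: OutputSpec = field(default_factory=OutputSpec)

    def validate(self) -> None:
        self.model.validate()
        self.experiment.validate()
        self.output.validate()

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model.to_dict(),
            "experiment": dataclasses.asdict(self.experiment),
            "output": dataclasses.asdict(self.output),
        }

    def resolved_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path) -> ScenarioConfig:
    """Parse a scenario file, merge with defaults, reject unknown keys."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - {"model", "experiment", "output"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    cfg = ScenarioConfig(
        model=ModelParams.from_dict(data.get("model", {})),
        experiment=_from_mapping(ExperimentSpec, data.get("experiment", {}), "experiment"),
        output=_from_mapping(OutputSpec, data.get("output", {}), "output"),
    )
    cfg.validate()
    return cfg


def write_provenance(cfg: ScenarioConfig, out_dir, seed: int | None = None) -> Path:
    """Write the resolved config, its hash, and the seed next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "config": cfg.to_dict(),
        "config_hash": cfg.resolved_hash(),
        "seed": cfg.experiment.seed_base if seed is None else seed,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
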