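"""Plain-text experiment configuration (flat YAML key/value schema).

Every key is optional and falls back to the package default.  Keys
prefixed ``arch.`` or ``dynamics.`` address the architecture and unit
dynamics; all other keys address the experiment grid.  Unknown keys are
rejected by name so typos fail loudly.

Example::

    conditions: [full_error_driven, full_hebbian]
    ca3_sizes: [40]
    set_sizes: [40, 200]
    n_seeds: 3
    master_seed: 1
    arch.n_slots: 8
    dynamics.dt_vm: 0.2
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .dynamics import DynamicsParams
from .network import ArchitectureConfig
from .experiments import ExperimentConfig

__all__ = ["ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """A configuration problem, naming the offending key."""


def config_from_dict(raw: dict) -> ExperimentConfig:
    exp_keys = {f.name for f in fields(ExperimentConfig)} - {"arch", "dynamics"}
    arch_keys = {f.name for f in fields(ArchitectureConfig)}
    dyn_keys = {f.name for f in fields(DynamicsParams)}

    exp: dict = {}
    arch: dict = {}
    dyn: dict = {}
    for key, value in raw.items():
        if key.startswith("arch."):
            sub = key[len("arch."):]
            if sub not in arch_keys:
                raise ConfigError(f"unknown architecture key: {key!r}")
            arch[sub] = value
        elif key.startswith("dynamics."):
            sub = key[len("dynamics."):]
            if sub not in dyn_keys:
                raise ConfigError(f"unknown dynamics key: {key!r}")
            dyn[sub] = value
        elif key in exp_keys:
            exp[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    try:
        config = ExperimentConfig(arch=ArchitectureConfig(**arch),
                                  dynamics=DynamicsParams(**dyn), **exp)
        config.dynamics.validate()
        config.validate()
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return config


def load_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)
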