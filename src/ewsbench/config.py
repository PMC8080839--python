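"""YAML (de)serialisation of parameter sets and scenario configurations."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .model import ModelParameters
from .scenarios import ScenarioConfig
from .simulate import NoiseSpec

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]


def params_to_dict(params: ModelParameters) -> dict:
    out = {}
    for key, val in asdict(params).items():
        out[key] = val.tolist() if isinstance(val, np.ndarray) else val
    return out


def params_from_dict(d: dict) -> ModelParameters:
    try:
        return ModelParameters(**d)
    except TypeError as exc:
        raise ConfigError(f"invalid model parameter keys: {exc}") from exc


def save_params(params: ModelParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def load_params(path) -> ModelParameters:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["noise"] = asdict(config.noise)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    noise = d.pop("noise", None)
    try:
        if noise is not None:
            d["noise"] = NoiseSpec(**noise)
        return ScenarioConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"invalid scenario keys: {exc}") from exc


def save_scenario(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def load_scenario(path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError("scenario config must be a mapping")
    return scenario_from_dict(data)
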