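"""Structured run configuration with environment-variable overrides.

The config is a single YAML file; any leaf can be overridden by an
environment variable ``HYDROSHAPE_<SECTION>__<KEY>`` (double underscore
separates nesting levels), so runs stay reproducible without hidden state.
Unknown keys are schema violations and are reported by name.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .constants import ThermoConstants
from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "ENV_PREFIX"]

ENV_PREFIX = "HYDROSHAPE_"


class ConstantsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dG_DDAA_kJ_mol: float = -2.66
    dG_water_water_cal_mol: float = -1500.0
    r_H2O_A: float = 1.9
    T_K: float = 293.0
    P_MPa: float = 0.1

    def to_thermo_constants(self) -> ThermoConstants:
        return ThermoConstants.from_config(self.model_dump())


class HBondConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r_OO_max_A: float = 3.5
    angle_OOH_max_deg: float = 30.0


class WhamConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bin_width_A: float = 0.1
    tolerance: float = Field(1e-7, gt=0)
    max_iter: int = 100_000


class RunConfig(BaseModel):
    """Top-level configuration shared by all pipeline stages."""

    model_config = ConfigDict(extra="forbid")

    constants: ConstantsConfig = ConstantsConfig()
    hbond: HBondConfig = HBondConfig()
    layer_cutoff_A: float = 3.5
    wham: WhamConfig = WhamConfig()
    seed: int = 0

    def show(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def _apply_env_overrides(data: dict, env: Mapping[str, str]) -> dict:
    for key, value in env.items():
        if not key.startswith(ENV_PREFIX):
            continue
        parts = key[len(ENV_PREFIX):].lower().split("__")
        node: Any = data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigurationError(f"cannot override non-section key via {key}")
        node[parts[-1]] = yaml.safe_load(value)
    return data


def _case_fold_keys(data: dict, model: type[BaseModel]) -> dict:
    """Map lowercased env-style keys back onto the model's field names."""
    fields = {name.lower(): name for name in model.model_fields}
    out = {}
    for key, value in data.items():
        name = fields.get(str(key).lower(), key)
        sub = model.model_fields.get(name)
        if (
            isinstance(value, dict)
            and sub is not None
            and isinstance(sub.annotation, type)
            and issubclass(sub.annotation, BaseModel)
        ):
            value = _case_fold_keys(value, sub.annotation)
        out[name] = value
    return out


def load_config(
    path: str | Path | None = None, env: Mapping[str, str] | None = None
) -> RunConfig:
    """Load a RunConfig from YAML (optional) plus environment overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(loaded)}")
        data = loaded
    data = _apply_env_overrides(data, os.environ if env is None else env)
    data = _case_fold_keys(data, RunConfig)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigurationError(f"config error at key '{loc}': {first['msg']}") from exc
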