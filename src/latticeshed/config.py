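"""Run configuration: flat YAML files mapping 1:1 onto SimParams.

A config file holds SimParams fields as top-level keys plus an optional
``calibration`` block overriding SheddingCalibration constants.  Presets for
the four model quadrants (proliferative/quiescent x driver-dependent/
independent, small and large sanctuary) ship with the package.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .lattice_engine import SimParams
from .shedding_model import SheddingCalibration, calibration_for

__all__ = [
    "ConfigError",
    "load_config",
    "params_to_dict",
    "list_presets",
    "preset_path",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration key."""


_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimParams)}
_CAL_FIELDS = {f.name for f in dataclasses.fields(SheddingCalibration)}


def load_config(path: str | Path) -> tuple[SimParams, SheddingCalibration]:
    """Parse a YAML run config into (SimParams, SheddingCalibration).

    Unknown keys are rejected.  Calibration constants not overridden are
    anchored at the run's own detection size (1% tumor fraction at
    detection), so desk-scale runs stay internally consistent.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    cal_block = raw.pop("calibration", {}) or {}
    unknown = set(raw) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown_cal = set(cal_block) - _CAL_FIELDS
    if unknown_cal:
        raise ConfigError(f"unknown calibration keys: {sorted(unknown_cal)}")
    try:
        params = SimParams(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    cal = calibration_for(params, **cal_block)
    return params, cal


def params_to_dict(params: SimParams) -> dict:
    return dataclasses.asdict(params)


def _preset_dir():
    return resources.files("latticeshed") / "presets"


def list_presets() -> list[str]:
    return sorted(p.name.removesuffix(".yaml") for p in _preset_dir().iterdir())


def preset_path(name: str) -> Path:
    p = _preset_dir() / f"{name}.yaml"
    if not p.is_file():
        raise ConfigError(f"no preset named {name!r}; available: {list_presets()}")
    return Path(str(p))
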