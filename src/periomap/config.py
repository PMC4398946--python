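"""Pipeline configuration: one YAML block, explicit seeds, strict keys."""
from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "subjects": [
        {"animal": "M1", "hemisphere": "L"},
        {"animal": "M1", "hemisphere": "R"},
    ],
    "sheet": {
        "extent_mm": [30.0, 20.0],
        "vertex_spacing_mm": 1.0,
    },
    "topography": {
        "centre_uv": [0.0, 0.0],
        "rate_decay_mm": 4.0,
        "freq_slope_oct_per_mm": 0.4,
        "amplitude_pct": 1.0,
        "tuning_width_oct": 1.5,
    },
    "noise": {
        "baseline": 100.0,
        "sd": 6.7,
        "ar1": 0.0,
    },
    "sparse": {
        "rate_volumes": 3780,
        "freq_volumes": 2160,
        "tr_s": 10.0,
        "ta_s": 1.0,
    },
    "glm": {
        "fwhm_mm": 2.0,
        "highpass_cutoff_s": 300.0,
        "alpha": 0.001,
        "correction": "none",
    },
    "projection": {
        "radius_mm": 1.6,
    },
    "gradients": {
        "fields": ["A1", "R", "CL"],
    },
    "phase": {
        "enabled": False,
        "hemodynamic_delay_s": 4.0,
        "corr_threshold": 0.2,
        "mode": "cycle",
        "noise_sd": 0.5,
    },
}


class ConfigError(ValueError):
    pass


def _check_keys(given: dict, schema: dict, path: str = "") -> None:
    for key, value in given.items():
        if key not in schema:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(schema[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path}{key} must be a mapping")
            _check_keys(value, schema[key], path=f"{path}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


class PipelineConfig:
    """Validated pipeline parameters; unknown keys are rejected up front."""

    def __init__(self, overrides: dict | None = None):
        overrides = overrides or {}
        _check_keys(overrides, DEFAULT_CONFIG)
        self.data = _merge(DEFAULT_CONFIG, overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(loaded)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hash(self) -> str:
        """Stable digest of the fully-resolved configuration."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    def __getitem__(self, key: str):
        return self.data[key]
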