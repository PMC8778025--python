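"""Pipeline configuration: nested config blocks for every stage,
YAML round-trip, strict key checking, and config hashing so artifacts
can be traced to the settings that produced them."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

_DEFAULTS = {
    "seed": 0,
    "out_dir": "semgdet_out",
    "synth": {
        "fs": 2000.0,
        "duration": 5.0,
        "n_per_class": 2,
        "burst": [1.0, 4.0],
        "peak_amplitude": 1.0,
        "mains_amplitude": 0.05,
        "drift_amplitude": 0.08,
        "noise_floor": 0.01,
    },
    "filter": {
        "band": [20.0, 450.0],
        "notch": 50.0,
        "order": 4,
        "notch_q": 30.0,
    },
    "segment": {"window": [2.0, 4.0]},
    "fusion": {"weights": None},   # None: uniform over retained channels
    "channels": {
        "retained": ["biceps_brachii", "triceps_brachii",
                     "extensor_carpi_ulnaris", "extensor_carpi_radialis"],
    },
    "imaging": {"size": 448, "segment_before_render": False},
    "mgnet": {
        "lr": 3e-4,
        "batch_size": 16,
        "max_epochs": 3000,
        "checkpoint_every": 200,
        "width_multiplier": 1.0,
        "input_size": 448,
        "alpha": 0.13,
        "beta": 0.26,
    },
    "detector": {
        "input_size": 416,
        "width_multiplier": 1.0,
        "neck_channels": 64,
        "iterations": 300,
        "lr": 1e-3,
        "conf_threshold": 0.3,
        "soft_nms_sigma": 0.5,
        "mosaic": False,
    },
    "angles": {"elbow": 135.0, "wrist_fe": 80.0, "wrist_ps": 90.0},
    "eval": {"iou_thresholds": "0.5:0.95:0.05"},
    "demo": {
        "n_per_class": 2,
        "image_size": 160,
        "classifier_size": 64,
        "width_multiplier": 0.25,
        "classifier_epochs": 15,
        "detector_iterations": 300,
    },
}


@dataclass
class PipelineConfig:
    """Validated nested configuration for the whole pipeline."""

    values: dict = field(default_factory=lambda: _deep_copy(_DEFAULTS))

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        merged = _deep_copy(_DEFAULTS)
        _merge(merged, overrides, path="")
        return cls(values=merged)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        return cls.from_dict(raw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))

    @property
    def hash(self) -> str:
        payload = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            _merge(base[key], value, here)
        else:
            base[key] = value
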