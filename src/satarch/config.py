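"""Pipeline configuration: flat YAML with per-stage namespaces.

Unknown keys are rejected with the offending key named; all randomness in a
pipeline run flows from the single top-level seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "periodicity": True,
        "classify": True,
        "phr": True,
        "rdna": True,
    },
    "inputs": {
        "fasta": None,  # required when simulate is disabled
        "truth_bed": None,
    },
    "simulate": {
        "scale": 1.0,
        "rdna_total_copies": 100,
        "mean_depth": 30.0,
        "noise_sd": 2.0,
        "bin_size": 500,
        "coding_methylation": 0.1,
        "igs_methylation": 0.8,
    },
    "periodicity": {
        "k": 21,
        "max_period": 3000,
    },
    "classify": {
        "min_margin": 2.0,
        "min_array_monomers": 10,
        "max_gap": 1000,
    },
    "phr": {
        "window": 5000,
        "step": 2500,
        "min_identity": 0.99,
        "min_span": 10000,
    },
    "rdna": {
        "activity_threshold": 0.5,
        "min_cdr_span": 10000,
        "dip_factor": 0.5,
    },
}


class PipelineConfig(dict):
    """Validated stage-namespaced configuration (a dict subclass)."""

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULTS)
        _merge(cfg, data, path="")
        return cls(cfg)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def _merge(base: dict, update: dict, path: str) -> None:
    for key, value in update.items():
        where = f"{path}{key}"
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where!r}")
        if isinstance(base[key], dict) and base[key]:
            if not isinstance(value, dict):
                raise ConfigError(f"key {where!r} must be a mapping")
            _merge(base[key], value, path=f"{where}.")
        else:
            base[key] = value


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config file, filling documented defaults."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file not parseable: {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    config.save(path)
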