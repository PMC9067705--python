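"""Run configuration: YAML/JSON config files, override precedence, manifests.

Precedence is CLI flags > config file > defaults. Every CLI run writes one
RunManifest (JSON) into its output directory recording the artifact
version, a hash of the effective configuration, the seeds and the paths
touched, so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__

__all__ = ["load_config", "merge_overrides", "config_hash", "RunManifest"]

DEFAULTS: dict = {
    "generate": {
        "n": 100,
        "seed": 0,
        "desk_scale": True,
        "clutter": False,
    },
    "prepare": {"target_shape": [320, 576]},
    "augment": {
        "multiplier": 16,
        "rotation_max_deg": 10.0,
        "translate_max_px": 24,
        "crop_fraction_range": [0.5, 0.9],
        "seed": 0,
    },
    "pairs": {"crop_factors": [0.25, 0.5, 0.75], "seed": 0},
    "train": {
        "ablation": "i",
        "K": 10,
        "lr": 1e-4,
        "epochs": 300,
        "lambda": 0.1,
        "epsilon": 0.0,
        "backbone": "tiny",
        "seed": 0,
    },
    "evaluate": {"noise_area_fraction": 0.02},
}


def load_config(path: str | Path | None) -> dict:
    """Defaults overlaid with a YAML or JSON config file (if given)."""
    config = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path is None:
        return config
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    for section, values in loaded.items():
        if section not in config:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in config[section]:
                raise ValueError(f"unknown config key {section}.{key!r}")
            config[section][key] = value
    return config


def merge_overrides(config: dict, section: str, overrides: dict) -> dict:
    """Apply non-None CLI overrides on top of a config section."""
    merged = dict(config[section])
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in merged:
            raise ValueError(f"unknown config key {section}.{key!r}")
        merged[key] = value
    return merged


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunManifest:
    subcommand: str
    config: dict
    seeds: list[int] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "subcommand": self.subcommand,
                    "version": self.version,
                    "config_hash": config_hash(self.config),
                    "config": self.config,
                    "seeds": self.seeds,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
                default=str,
            )
        return path
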