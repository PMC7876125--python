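"""Run configuration: defaults, YAML loading, validation, hashing.

A run configuration is a nested dict fully serialisable to YAML; persisting a
config and re-running reproduces identical outputs because every stochastic
stage is seeded from ``seed``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["ConfigError", "DEFAULT_CONFIG", "default_config", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid configuration; ``keys`` lists the offending key paths."""

    def __init__(self, keys: list[str]):
        self.keys = keys
        super().__init__("invalid configuration keys: " + ", ".join(keys))


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "alpha": 0.05,
    "synth": {
        "receptor_color": [230.0, 200.0, 60.0],
        "paper_color": [250.0, 250.0, 245.0],
        "slope_m": 0.8,
        "conc_max": 100.0,
        "noise_sd": 2.0,
        "illum_gradient": 0.02,
        "zone_center": [32.0, 32.0],
        "zone_radius": 20.0,
        "frame_size": 64,
        "device_rsd": 0.0377,
    },
    "roi": {"mode": "fixed-circle", "center_row": 32.0, "center_col": 32.0, "radius_px": 20.0},
    "calibration": {
        "range": [1.0, 100.0],
        "concentrations": [1.0, 20.0, 40.0, 60.0, 80.0, 100.0],
        "n_replicates": 5,
        "n_blanks": 20,
    },
    "reproducibility": {"concentration": 40.0, "n_devices": 5},
    "stability": {"n_days": 30, "stable_until_day": 20, "drift_rate": 0.08},
    "optimization": {
        "levels": [0.5, 1.0, 2.0, 3.0, 4.0],
        "relative_profile": [0.55, 0.8, 1.0, 0.85, 0.6],
        "n_replicates": 3,
    },
    "interference": {
        "analyte_conc": 40.0,
        "ratios": [20.0, 50.0, 100.0, 500.0],
        "species_tolerance": {
            "Na+": 500, "K+": 500, "Ca2+": 500, "Fe3+": 500, "Glucose": 500,
            "Urea": 50, "SO3^2-": 50, "Cl-": 50,
            "I-": 20, "SCN-": 20,
        },
        "interfering_effect": 0.08,
    },
}

_SCALAR_TYPES = {
    "seed": int,
    "alpha": float,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict, prefix: str, bad: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            bad.append(path)
            continue
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                bad.append(path)
                continue
            # species_tolerance is an open mapping; replace wholesale
            if key == "species_tolerance":
                out[key] = dict(val)
            else:
                out[key] = _merge(base[key], val, path + ".", bad)
        else:
            out[key] = val
    return out


def _validate(cfg: dict, bad: list[str]) -> None:
    for key, typ in _SCALAR_TYPES.items():
        try:
            typ(cfg[key])
        except (TypeError, ValueError):
            bad.append(key)
    for key in ("n_replicates", "n_blanks"):
        if int(cfg["calibration"].get(key, 1)) < 1:
            bad.append(f"calibration.{key}")
    if len(cfg["optimization"]["levels"]) != len(cfg["optimization"]["relative_profile"]):
        bad.append("optimization.relative_profile")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over the defaults; validate.

    Unknown keys, type mismatches and structural problems raise
    :class:`ConfigError` listing every offending key path.
    """
    bad: list[str] = []
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(["<root>"])
        cfg = _merge(cfg, user, "", bad)
    if overrides:
        cfg = _merge(cfg, overrides, "", bad)
    if not bad:
        _validate(cfg, bad)
    if bad:
        raise ConfigError(bad)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable digest of a config, stamped into output manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode("utf8")
    return hashlib.sha256(blob).hexdigest()[:12]
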