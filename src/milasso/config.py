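"""Run configuration: defaults, YAML loading, stable hashing."""

from __future__ import annotations

import copy
import hashlib
import json
import os

import yaml

DEFAULTS: dict = {
    "impute": {"m": 10},
    "lasso": {"tol": 1e-7, "max_iter": 100_000, "n_lambda": 100, "ratio": 1e-3},
    "cv": {"folds": 10},
    "stepwise": {"penter": 0.05, "premove": 0.10, "max_steps": 500},
    "pooling": {"retain": 0.8},
    "chem": {
        "constant_set": "auto",
        "proton_floor": 1e-12,
        "nitrate_poly": {"c0": 0.0, "c_dx": 60.0, "c_dx2": 0.0,
                         "c_n0": 0.0, "c_n02": 0.0, "c_cross": 0.0},
        "ph_residual": {"intercept": 0.0, "coef_dN": 0.0,
                        "coef_dP": 0.0, "coef_vvm": 0.0},
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | os.PathLike | None = None) -> dict:
    """Defaults overlaid with a YAML file (missing keys keep defaults)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
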