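"""Structured configuration: defaults, validation, normalization.

One YAML file with sections mirroring the analysis stages.  Every parameter
has a documented default; unknown keys and out-of-range values are reported
together, not one at a time.
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .errors import ConfigError

__all__ = ["DEFAULTS", "validate_config", "load_config", "config_hash"]

DEFAULTS: dict = {
    "selections": {
        # helix faces as residue lists (Cα atoms); overridable
        "side1_residues": [3, 6, 7, 18],
        "side2_residues": [1, 12, 16],
        "phosphate": "membrane phosphate atoms",
        "tracked": "peptide all",
    },
    "funnel": {
        "alpha_rad": 0.8,
        "rcyl_A": 1.0,
        "zcc_A": 35.0,
        "zmax_A": 45.0,
        "k_wall": 10.0,
    },
    "contact": {
        "r0": 5.0,
        "n": 8,
        "m": 16,
        "threshold": 0.5,
        "normalization": "per-group-atom",
    },
    "clustering": {
        "n_clusters": 10,
        "core_start": 5,
        "core_stop": 12,
        "max_frames": 800,
    },
    "order_parameters": {
        "chains": ["c1", "c2"],
        "h_mode": "explicit",
        "n_blocks": 5,
    },
    "simulation": {
        "temperature_K": 300.0,
        "friction_ps": 0.2,
        "dt_fs": 10.0,
        "n_steps": 500_000,
        "stride": 250,
        "seed": 0,
    },
    "io": {
        "trajectory": None,
        "trajectory_b": None,
        "output_dir": ".",
    },
}

_RANGE_CHECKS = {
    ("contact", "r0"): lambda v: v > 0,
    ("contact", "n"): lambda v: isinstance(v, int) and v > 0 and v % 2 == 0,
    ("contact", "m"): lambda v: isinstance(v, int) and v > 0 and v % 2 == 0,
    ("contact", "threshold"): lambda v: 0.0 <= v <= 10.0,
    ("funnel", "alpha_rad"): lambda v: 0 < v < 1.5707963,
    ("funnel", "rcyl_A"): lambda v: v > 0,
    ("funnel", "zcc_A"): lambda v: v > 0,
    ("funnel", "k_wall"): lambda v: v > 0,
    ("clustering", "n_clusters"): lambda v: isinstance(v, int) and v >= 1,
    ("simulation", "temperature_K"): lambda v: v > 0,
    ("simulation", "dt_fs"): lambda v: v > 0,
}


def validate_config(raw: dict | None) -> dict:
    """Fill defaults and report every unknown key / bad value at once.

    Returns the fully-normalized nested dict; raises :class:`ConfigError`
    with the aggregated problem list otherwise.
    """
    raw = raw or {}
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top-level configuration must be a mapping"])
    normalized = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
    for section, content in raw.items():
        if section not in DEFAULTS:
            problems.append(f"unknown section {section!r}")
            continue
        if not isinstance(content, dict):
            problems.append(f"section {section!r} must be a mapping")
            continue
        for key, value in content.items():
            if key not in DEFAULTS[section]:
                problems.append(f"unknown key {section}.{key}")
                continue
            check = _RANGE_CHECKS.get((section, key))
            if check is not None:
                try:
                    ok = check(value)
                except TypeError:
                    ok = False
                if not ok:
                    problems.append(f"invalid value for {section}.{key}: {value!r}")
                    continue
            normalized[section][key] = value
    n, m = normalized["contact"]["n"], normalized["contact"]["m"]
    if not n < m:
        problems.append(f"contact.n ({n}) must be smaller than contact.m ({m})")
    if problems:
        raise ConfigError(problems)
    return normalized


def load_config(path) -> dict:
    """Parse a YAML config file and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def config_hash(config: dict) -> str:
    """Stable short hash of a normalized config, for provenance stamping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
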