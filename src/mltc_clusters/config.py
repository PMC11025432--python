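"""YAML configuration handling shared by the CLI commands."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .simulate import SimConfig


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file; an absent path yields an empty config."""
    if path is None:
        return {}
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    cfg["_config_hash"] = hashlib.sha256(text.encode()).hexdigest()[:16]
    return cfg


def sim_config_from_dict(cfg: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from the ``simulate:`` section of a config dict.

    Scalar fields override dataclass defaults; the nested
    ``baseline_logit`` and ``covariate_effects`` mappings are merged over
    the defaults key by key.
    """
    section = dict(cfg.get("simulate", {}))
    base = SimConfig()
    for nested in ("baseline_logit", "covariate_effects"):
        if nested in section:
            merged = getattr(base, nested)
            for key, val in section[nested].items():
                if isinstance(val, dict):
                    merged[key] = {**merged.get(key, {}), **val}
                else:
                    merged[key] = val
            section[nested] = merged
    if seed is not None:
        section["seed"] = int(seed)
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    if "onset_median_range" in section:
        section["onset_median_range"] = tuple(section["onset_median_range"])
    if "onset_spread_range" in section:
        section["onset_spread_range"] = tuple(section["onset_spread_range"])
    return SimConfig(**section)


def write_metadata(path: str | Path, seed: int, cfg: dict, **extra) -> None:
    """Write a small JSON metadata block next to an output file."""
    meta = {
        "seed": seed,
        "config_hash": cfg.get("_config_hash"),
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
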