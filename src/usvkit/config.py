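"""YAML configuration: detector profiles, STFT geometry, simulation plans.

Schema (version 1)::

    version: 1
    stft:
      window_length: 1024
      overlap_fraction: 0.9
      fs: 250000
    profiles:
      usv50: {k_sd: 2.1, min_bands: 4, ...}   # any DetectorProfile field
      usv22: {...}

CLI flags override config values; config values override the published
defaults.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .detection import PROFILES, DetectorProfile
from .spectral import StftParams

__all__ = ["load_config", "profile_from_config", "stft_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    version = cfg.get("version", 1)
    if version != 1:
        raise ValueError(f"unsupported config version {version!r}")
    return cfg


def profile_from_config(cfg: dict | None, name: str) -> DetectorProfile:
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; expected one of {sorted(PROFILES)}")
    base = PROFILES[name]
    if not cfg:
        return base
    overrides = (cfg.get("profiles") or {}).get(name) or {}
    if "pass_offsets_s" in overrides:
        overrides["pass_offsets_s"] = tuple(overrides["pass_offsets_s"])
    return replace(base, **overrides)


def stft_from_config(cfg: dict | None, fs: float | None = None) -> StftParams:
    overrides = dict((cfg or {}).get("stft") or {})
    if fs is not None:
        overrides["fs"] = fs
    return StftParams(**overrides)
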