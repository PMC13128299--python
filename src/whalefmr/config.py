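"""Configuration: defaults mirroring the study parameters, plus YAML I/O.

The ``surface_periods`` block mirrors the per-period parameter table
column-for-column (respiration rate mean and CI, tidal-volume proportion
range of vital capacity, oxygen extraction mean, daily minutes).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .respiration import DEFAULT_SURFACE_PERIODS, SurfacePeriodSpec

__all__ = ["default_config", "load_config", "periods_from_config"]


def default_config() -> dict:
    return {
        "morphometrics": {
            "length_mean_m": 8.61,
            "length_sd_m": 0.89,
            "length_floor_m": 4.0,
            "beta_admr": 2.0,
        },
        "surface_periods": [
            {
                "period_id": p.period_id,
                "fr_mean": p.fr_mean,
                "fr_ci": list(p.fr_ci),
                "vt_prop_range": list(p.vt_prop_range),
                "vt_sd_frac": p.vt_sd_frac,
                "eo2_mean": p.eo2_mean,
                "eo2_concentration": p.eo2_concentration,
                "daily_minutes": p.daily_minutes,
                "daily_prop_ci": list(p.daily_prop_ci) if p.daily_prop_ci else None,
            }
            for p in DEFAULT_SURFACE_PERIODS
        ],
        "respiration": {"n_iter": 10_000},
        "odba_sim": {"n_iter": 1000, "n_individuals": 10, "n_dives": 100},
        "odba_signal": {
            "highpass_hz": 0.068,
            "gate_angle_deg": 25.0,
            "min_valid_frac": 0.5,
            "odba_scale": 1.0,
        },
    }


def load_config(path) -> dict:
    """Load a YAML config, overlaying it onto the defaults (shallow merge
    per top-level block)."""
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = cfg[k] | v
        else:
            cfg[k] = v
    return cfg


def periods_from_config(cfg: dict) -> list[SurfacePeriodSpec]:
    out = []
    for block in cfg["surface_periods"]:
        out.append(SurfacePeriodSpec(
            period_id=int(block["period_id"]),
            fr_mean=float(block["fr_mean"]),
            fr_ci=tuple(block["fr_ci"]),
            vt_prop_range=tuple(block["vt_prop_range"]),
            eo2_mean=float(block["eo2_mean"]),
            daily_minutes=float(block["daily_minutes"]),
            vt_sd_frac=float(block.get("vt_sd_frac", 0.1)),
            eo2_concentration=float(block.get("eo2_concentration", 50.0)),
            daily_prop_ci=(tuple(block["daily_prop_ci"])
                           if block.get("daily_prop_ci") else None),
        ))
    return out
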