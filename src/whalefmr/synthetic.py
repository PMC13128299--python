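"""Synthetic DTAG-like data with the statistical structure the analysis assumes.

Generates, per simulated individual: a dive table (alternating foraging
dives with descent/bottom/ascent phases and post-dive surfacings), breath
event times (renewal process with period-specific rates), and tri-axial
accelerometer + magnetometer + depth streams (gravity + fluking sinusoid +
pitch-rotation oscillation + noise), including a ground-truth specific-
acceleration channel for oracle tests.

The generator emulates the field situation — 45-50-min foraging dives,
~9-min post-dive surfacings, a roughly 60/10/30 daily split between diving,
post-dive surfacing and non-foraging surface time, and fluking at 0.17 Hz —
not any particular deployment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .divesim import DivePhaseParams, default_dive_params
from .morphometrics import as_rng
from .respiration import (
    DEFAULT_SURFACE_PERIODS,
    SURFACE_THRESHOLD_MIN,
    SurfacePeriodSpec,
    segment_surface_table,
)

__all__ = [
    "SyntheticTagConfig",
    "generate_dive_table",
    "surface_table",
    "time_budget",
    "generate_respiration_events",
    "generate_sensor_stream",
    "generate_tag_dataset",
]

_G = 9.81


@dataclass
class SyntheticTagConfig:
    """Knobs of the synthetic tag generator.

    The long-surface occurrence probability and duration are chosen so a
    long deployment spends ~60% of its time diving, ~10% in post-dive
    surfacing and ~30% in non-foraging surface time: with a ~47-min mean
    dive, a ~9-min post-dive surfacing and a 0.3 chance of a ~74-min
    non-foraging block per cycle, the expected cycle is ~78 min of which
    60%/11%/29% fall in the three states.
    """

    n_individuals: int = 7
    deployment_hours_range: tuple[float, float] = (4.46, 24.67)
    dive_params: DivePhaseParams = field(default_factory=default_dive_params)
    postdive_surface_mean_min: float = 9.0
    postdive_surface_sd_min: float = 1.0
    long_surface_prob: float = 0.3
    long_surface_mean_min: float = 74.4
    long_surface_sd_min: float = 25.0
    fr_periods: tuple[SurfacePeriodSpec, ...] = DEFAULT_SURFACE_PERIODS
    fs_hz: float = 25.0
    fluking_hz: float = 0.17
    # fluking specific-acceleration amplitude (m/s^2) per behavioural state
    fluking_amp: dict = field(default_factory=lambda: {
        "descent": 0.30, "bottom": 0.60, "ascent": 0.40, "surface": 0.05})
    # pitch-oscillation amplitude (rad) per state (rotation contamination)
    rotation_amp: dict = field(default_factory=lambda: {
        "descent": 0.10, "bottom": 0.10, "ascent": 0.10, "surface": 0.0})
    pitch_deg: dict = field(default_factory=lambda: {
        "descent": -55.0, "bottom": 0.0, "ascent": 55.0, "surface": 0.0})
    depth_bottom_m: float = 800.0
    accel_noise_sd: float = 0.02
    mag_noise_sd: float = 0.2
    mag_field_strength: float = 40.0
    mag_inclination_deg: float = 55.0


def _trunc_normal(mean, sd, rng, lo=0.0):
    if sd == 0:
        return float(mean)
    x = rng.normal(mean, sd)
    while x <= lo:
        x = rng.normal(mean, sd)
    return float(x)


def generate_dive_table(config: SyntheticTagConfig, rng=None,
                        deployment_s: float | None = None) -> pd.DataFrame:
    """Alternating dive/surface records covering one deployment.

    Columns: dive_id, start_s, descent_end_s, bottom_end_s, end_s (ascent
    end), surface_end_s (start of the next dive, or deployment end) and a
    ``truncated`` flag set when the deployment ends mid-dive.
    """
    rng = as_rng(rng)
    if deployment_s is None:
        lo, hi = config.deployment_hours_range
        deployment_s = rng.uniform(lo, hi) * 3600.0
    p = config.dive_params
    rows = []
    t = 0.0
    dive_id = 0
    while t < deployment_s:
        dur = rng.multivariate_normal(
            p.duration_mean, np.outer(p.duration_sd, p.duration_sd) * p.duration_corr,
            check_valid="ignore", method="svd")
        while (dur <= 0).any():
            dur = rng.multivariate_normal(
                p.duration_mean,
                np.outer(p.duration_sd, p.duration_sd) * p.duration_corr,
                check_valid="ignore", method="svd")
        d_s, b_s, a_s = dur * 60.0
        end = t + d_s + b_s + a_s
        truncated = end > deployment_s
        surf_min = _trunc_normal(config.postdive_surface_mean_min,
                                 config.postdive_surface_sd_min, rng)
        if rng.uniform() < config.long_surface_prob:
            surf_min += _trunc_normal(config.long_surface_mean_min,
                                      config.long_surface_sd_min, rng)
        surf_end = end + surf_min * 60.0
        rows.append({
            "dive_id": dive_id,
            "start_s": t,
            "descent_end_s": min(t + d_s, deployment_s),
            "bottom_end_s": min(t + d_s + b_s, deployment_s),
            "end_s": min(end, deployment_s),
            "surface_end_s": min(surf_end, deployment_s),
            "truncated": truncated,
        })
        t = surf_end
        dive_id += 1
    return pd.DataFrame(rows)


def surface_table(dive_table: pd.DataFrame) -> pd.DataFrame:
    """Post-dive surfacing intervals (start_s, end_s) from a dive table."""
    out = dive_table[dive_table["surface_end_s"] > dive_table["end_s"]]
    return pd.DataFrame({"start_s": out["end_s"].to_numpy(),
                         "end_s": out["surface_end_s"].to_numpy()})


def time_budget(dive_table: pd.DataFrame, deployment_s: float) -> dict:
    """Fractions of the deployment spent diving / post-dive / non-foraging.

    Post-dive surfacing counts up to the 9-min standardized threshold per
    surfacing; the excess is non-foraging surface time.
    """
    diving = float((dive_table["end_s"] - dive_table["start_s"]).sum())
    thr = SURFACE_THRESHOLD_MIN * 60.0
    surf = (dive_table["surface_end_s"] - dive_table["end_s"]).clip(lower=0.0)
    postdive = float(surf.clip(upper=thr).sum())
    rest = deployment_s - diving - postdive
    return {"diving": diving / deployment_s,
            "postdive": postdive / deployment_s,
            "nonforaging": rest / deployment_s}


def generate_respiration_events(
    segments: pd.DataFrame,
    periods=DEFAULT_SURFACE_PERIODS,
    rng=None,
) -> pd.DataFrame:
    """Breath event times over per-period surface segments.

    Events form a renewal process with exponential inter-breath intervals
    at each period's mean rate — the simplest process consistent with the
    modelled mean rates.

    Parameters
    ----------
    segments : DataFrame with ``start_s``, ``end_s``, ``period_id``
        (e.g. from :func:`whalefmr.respiration.segment_surface_table`).

    Returns a DataFrame with ``t_s`` and ``period_id``.
    """
    rng = as_rng(rng)
    rates = {p.period_id: p.fr_mean / 60.0 for p in periods}  # breaths/s
    rows = []
    for seg in segments.itertuples(index=False):
        rate = rates[int(seg.period_id)]
        if rate <= 0:
            continue
        t = seg.start_s + rng.exponential(1.0 / rate)
        while t < seg.end_s:
            rows.append({"t_s": t, "period_id": int(seg.period_id)})
            t += rng.exponential(1.0 / rate)
    return pd.DataFrame(rows, columns=["t_s", "period_id"])


def _phase_labels(t: np.ndarray, dive_table: pd.DataFrame) -> np.ndarray:
    """0 surface, 1 descent, 2 bottom, 3 ascent."""
    lab = np.zeros(t.size, dtype=np.int8)
    for d in dive_table.itertuples(index=False):
        lab[(t >= d.start_s) & (t < d.descent_end_s)] = 1
        lab[(t >= d.descent_end_s) & (t < d.bottom_end_s)] = 2
        lab[(t >= d.bottom_end_s) & (t < d.end_s)] = 3
    return lab


def _smooth(x: np.ndarray, fs: float, tau_s: float = 5.0) -> np.ndarray:
    """Moving-average smoothing so state changes are gradual, not steps."""
    w = max(int(round(tau_s * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def generate_sensor_stream(
    dive_table: pd.DataFrame,
    config: SyntheticTagConfig,
    rng=None,
    deployment_s: float | None = None,
) -> pd.DataFrame:
    """Tri-axial accelerometer/magnetometer/depth stream for one deployment.

    Per sample: body pitch = state pitch (descent down, ascent up) plus a
    fluking-frequency pitch oscillation (rotation contamination); the
    accelerometer reads gravity rotated into the body frame plus the true
    fluking specific acceleration (surge + heave sinusoids at 0.17 Hz with
    state-specific amplitude) plus white noise; the magnetometer reads the
    Earth's field rotated by heading and pitch plus noise.  Ground-truth
    specific acceleration is stored in ``sa_x/sa_y/sa_z`` for oracle tests.

    Heading is constant per deployment (rotation is purely about the body's
    lateral axis, matching the estimator's observability assumption).
    """
    rng = as_rng(rng)
    if deployment_s is None:
        deployment_s = float(dive_table["surface_end_s"].iloc[-1])
    fs = config.fs_hz
    n = int(round(deployment_s * fs))
    t = np.arange(n) / fs
    lab = _phase_labels(t, dive_table)
    names = np.array(["surface", "descent", "bottom", "ascent"])

    state_pitch = np.deg2rad(np.array(
        [config.pitch_deg[s] for s in names]))[lab]
    rot_amp = np.array([config.rotation_amp[s] for s in names])[lab]
    flk_amp = np.array([config.fluking_amp[s] for s in names])[lab]
    state_pitch = _smooth(state_pitch, fs)
    rot_amp = _smooth(rot_amp, fs)
    flk_amp = _smooth(flk_amp, fs)

    w = 2.0 * np.pi * config.fluking_hz
    phase0 = rng.uniform(0, 2 * np.pi)
    pitch = state_pitch + rot_amp * np.sin(w * t + phase0)

    # true specific acceleration: fluking surge (x) and heave (z)
    sa = np.zeros((n, 3))
    sa[:, 0] = flk_amp * np.sin(w * t + phase0 + rng.uniform(0, 2 * np.pi))
    sa[:, 2] = 0.5 * flk_amp * np.sin(w * t + phase0 + rng.uniform(0, 2 * np.pi))

    # gravity in body frame under pitch (rotation about lateral axis)
    acc = np.empty((n, 3))
    acc[:, 0] = -_G * np.sin(pitch)
    acc[:, 1] = 0.0
    acc[:, 2] = _G * np.cos(pitch)
    acc += sa + rng.normal(0.0, config.accel_noise_sd, size=(n, 3))

    # Earth's field: heading-rotated into the body x-y plane, then pitched
    inc = np.deg2rad(config.mag_inclination_deg)
    heading = rng.uniform(0, 2 * np.pi)
    b = config.mag_field_strength
    ux = b * np.cos(inc) * np.cos(heading)
    uy = -b * np.cos(inc) * np.sin(heading)
    uz = -b * np.sin(inc)
    mag = np.empty((n, 3))
    mag[:, 0] = ux * np.cos(pitch) - uz * np.sin(pitch)
    mag[:, 1] = uy
    mag[:, 2] = ux * np.sin(pitch) + uz * np.cos(pitch)
    mag += rng.normal(0.0, config.mag_noise_sd, size=(n, 3))

    # piecewise-linear depth consistent with the phases
    depth = np.zeros(n)
    for d in dive_table.itertuples(index=False):
        dd = config.depth_bottom_m
        m = (t >= d.start_s) & (t < d.descent_end_s)
        span = max(d.descent_end_s - d.start_s, 1e-9)
        depth[m] = (t[m] - d.start_s) / span * dd
        m = (t >= d.descent_end_s) & (t < d.bottom_end_s)
        depth[m] = dd
        m = (t >= d.bottom_end_s) & (t < d.end_s)
        span = max(d.end_s - d.bottom_end_s, 1e-9)
        depth[m] = dd * (1.0 - (t[m] - d.bottom_end_s) / span)
    depth += np.abs(rng.normal(0.0, 1.0, size=n))
    depth[lab == 0] = np.abs(rng.normal(0.0, 0.3, size=int((lab == 0).sum())))

    return pd.DataFrame({
        "t_s": t,
        "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2],
        "mx": mag[:, 0], "my": mag[:, 1], "mz": mag[:, 2],
        "depth_m": depth,
        "sa_x": sa[:, 0], "sa_y": sa[:, 1], "sa_z": sa[:, 2],
        "phase": names[lab],
    })


def generate_tag_dataset(config: SyntheticTagConfig, outdir,
                         seed: int | None = None) -> dict:
    """Write dive tables, breath events and sensor CSVs for all individuals.

    Returns (and writes as ``manifest.json``) a manifest mapping individual
    ids to their file paths and deployment lengths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = as_rng(seed)
    manifest = {"seed": seed, "individuals": {}}
    for i in range(config.n_individuals):
        ind = f"sw{i + 1:02d}"
        lo, hi = config.deployment_hours_range
        dep_s = rng.uniform(lo, hi) * 3600.0
        dives = generate_dive_table(config, rng, deployment_s=dep_s)
        segs = segment_surface_table(surface_table(dives))
        breaths = generate_respiration_events(segs, config.fr_periods, rng)
        stream = generate_sensor_stream(dives, config, rng, deployment_s=dep_s)

        dives_path = outdir / f"{ind}_dives.csv"
        breaths_path = outdir / f"{ind}_breaths.csv"
        sensor_path = outdir / f"{ind}_sensors.csv"
        dives.to_csv(dives_path, index=False)
        breaths.to_csv(breaths_path, index=False)
        stream.to_csv(sensor_path, index=False)
        (outdir / f"{ind}_sensors.json").write_text(json.dumps(
            {"fs_hz": config.fs_hz, "units": "m/s^2", "individual_id": ind}))
        manifest["individuals"][ind] = {
            "deployment_hours": dep_s / 3600.0,
            "dive_table": dives_path.name,
            "breaths": breaths_path.name,
            "sensors": sensor_path.name,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
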