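"""Tri-axial tag streams to minute-level, median-normalized ODBA.

Pipeline: high-pass filter the accelerometer to strip gravity/orientation
(dynamic acceleration, DA); remove rotation-induced components estimated
from the magnetometer to obtain specific acceleration (SA); average the
per-sample L1 norm |SAx|+|SAy|+|SAz| over 1-min windows; normalize each
individual's series to a common median so tag calibration differences drop
out.

In whales longer than a few metres, body rotations during fluking dominate
DA: as the body oscillates in pitch, the gravity vector sweeps through the
body frame inside the filter passband.  The rotation angle about the lateral
(y) axis is observable from the magnetometer — the Earth's field is fixed in
the inertial frame, so its apparent rotation in the body x-z plane tracks
body pitch oscillation — except when the field lies close to the rotation
axis, where the projection degenerates; those samples are gated out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .respiration import SURFACE_THRESHOLD_MIN  # noqa: F401  (shared convention)

__all__ = [
    "TriaxialRecord",
    "DEFAULT_HIGHPASS_HZ",
    "FLUKING_HZ",
    "highpass",
    "specific_acceleration",
    "odba_minutely",
    "normalize_odba",
    "trim_deployment",
    "odba_from_record",
]

FLUKING_HZ = 0.17                      # dominant sperm whale fluking frequency
DEFAULT_HIGHPASS_HZ = 0.4 * FLUKING_HZ  # = 0.068 Hz
DEFAULT_GATE_ANGLE_DEG = 25.0
_FILTER_ORDER = 4


@dataclass
class TriaxialRecord:
    """One deployment's sensor streams at a fixed sampling rate.

    ``acc`` and ``mag`` are (n, 3) arrays in the tag/body frame
    (x surge, y sway/lateral, z heave); ``depth`` is metres (>= 0);
    ``t`` is seconds since deployment start, strictly increasing at ``fs``.
    """

    t: np.ndarray
    acc: np.ndarray
    mag: np.ndarray
    depth: np.ndarray
    fs: float
    individual_id: str = ""
    units: str = "m/s^2"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.t.size
        if self.acc.shape != (n, 3) or self.mag.shape != (n, 3):
            raise ValueError("acc and mag must be (n, 3) arrays aligned with t")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @classmethod
    def from_csv(cls, csv_path, sidecar_path=None) -> "TriaxialRecord":
        """Read a sensor CSV (t_s, ax..az, mx..mz, depth_m) + JSON sidecar."""
        csv_path = Path(csv_path)
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".json")
        meta = json.loads(Path(sidecar_path).read_text())
        df = pd.read_csv(csv_path)
        return cls(
            t=df["t_s"].to_numpy(),
            acc=df[["ax", "ay", "az"]].to_numpy(),
            mag=df[["mx", "my", "mz"]].to_numpy(),
            depth=df["depth_m"].to_numpy(),
            fs=float(meta["fs_hz"]),
            individual_id=str(meta.get("individual_id", "")),
            units=str(meta.get("units", "m/s^2")),
        )


def _sos(kind: str, cutoff: float, fs: float):
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be in (0, Nyquist={fs / 2})")
    return signal.butter(_FILTER_ORDER, cutoff, btype=kind, fs=fs, output="sos")


def highpass(x, fs: float, cutoff: float = DEFAULT_HIGHPASS_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass along axis 0.

    The default cutoff is 0.4x the dominant fluking frequency (0.4 * 0.17 =
    0.068 Hz): static/orientation components are rejected while fluking
    oscillations pass essentially unattenuated.  Forward-backward filtering
    preserves phase so the rotation estimate can be subtracted in-phase.
    """
    x = np.asarray(x, dtype=float)
    return signal.sosfiltfilt(_sos("highpass", cutoff, fs), x, axis=0)


def _lowpass(x, fs: float, cutoff: float) -> np.ndarray:
    return signal.sosfiltfilt(_sos("lowpass", cutoff, fs), np.asarray(x, float), axis=0)


def specific_acceleration(
    dyn_acc: np.ndarray,
    mag: np.ndarray,
    static_acc: np.ndarray,
    fs: float,
    gate_angle_deg: float = DEFAULT_GATE_ANGLE_DEG,
    fluking_hz: float = FLUKING_HZ,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove rotation-induced acceleration from dynamic acceleration.

    The body's pitch oscillation angle phi(t) about the lateral (y) axis is
    estimated from the magnetometer: the Earth's field is inertially fixed,
    so the angle of its projection onto the body x-z plane,
    ``theta = atan2(mz, mx)``, equals a constant plus phi.  theta is
    low-pass smoothed at 2x the fluking frequency (noise control), unwrapped
    and high-passed to isolate the oscillatory rotation.  The rotation-
    induced dynamic acceleration is the gravity vector (static acceleration)
    swept through the rotating frame:

        pred_x = gx*(cos phi - 1) - gz*sin phi
        pred_z = gx*sin phi + gz*(cos phi - 1)

    and SA = DA - highpass(pred).

    Samples are flagged invalid (mask False) when the magnetic field lies
    within ``gate_angle_deg`` of the rotation (y) axis — there the x-z
    projection degenerates and the angle estimate is unreliable — or when
    the field vector has zero norm.

    Parameters
    ----------
    dyn_acc : (n, 3) high-pass filtered acceleration.
    mag : (n, 3) magnetometer stream (any consistent units).
    static_acc : (n, 3) low-frequency (gravity) acceleration, i.e. the raw
        acceleration minus ``dyn_acc``.
    fs : sampling rate, Hz.

    Returns
    -------
    (sa, valid) : SA stream (n, 3) and boolean validity mask (n,).
    """
    dyn_acc = np.asarray(dyn_acc, dtype=float)
    mag = np.asarray(mag, dtype=float)
    static_acc = np.asarray(static_acc, dtype=float)
    n = dyn_acc.shape[0]
    if mag.shape != (n, 3) or static_acc.shape != (n, 3):
        raise ValueError("dyn_acc, mag, static_acc must share shape (n, 3)")

    norm = np.linalg.norm(mag, axis=1)
    valid = norm > 0
    # gate: angle(field, y-axis) < threshold on either pole
    cos_gate = np.cos(np.deg2rad(gate_angle_deg))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_to_axis = np.abs(mag[:, 1]) / np.where(norm > 0, norm, np.nan)
    valid &= ~(cos_to_axis >= cos_gate)

    theta = np.unwrap(np.arctan2(mag[:, 2], mag[:, 0]))
    smooth_hz = min(2.0 * fluking_hz, 0.45 * fs)
    theta = _lowpass(theta, fs, smooth_hz)
    phi = highpass(theta, fs, highpass_hz)

    gx = static_acc[:, 0]
    gz = static_acc[:, 2]
    pred = np.zeros_like(dyn_acc)
    pred[:, 0] = gx * (np.cos(phi) - 1.0) - gz * np.sin(phi)
    pred[:, 2] = gx * np.sin(phi) + gz * (np.cos(phi) - 1.0)
    pred = highpass(pred, fs, highpass_hz)

    return dyn_acc - pred, valid


def odba_minutely(
    sa: np.ndarray,
    valid: np.ndarray | None = None,
    fs: float = 25.0,
    window_s: float = 60.0,
    min_valid_frac: float = 0.5,
) -> pd.DataFrame:
    """Minute-level ODBA: mean per-sample L1 norm over each window.

    ODBA for a window is the average of |SAx|+|SAy|+|SAz| over its valid
    samples (a rate — window length and sampling rate cancel, matching the
    mean-ODBA convention of the locomotion-cost calibration).  Windows whose
    valid fraction falls below ``min_valid_frac`` are reported as NaN, not
    zero.

    Returns a DataFrame with ``minute_index``, ``odba_raw``,
    ``valid_fraction``.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    sa = np.asarray(sa, dtype=float)
    n = sa.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    l1 = np.sum(np.abs(sa), axis=1)

    per_win = max(int(round(window_s * fs)), 1)
    n_win = int(np.ceil(n / per_win))
    rows = []
    for w in range(n_win):
        sl = slice(w * per_win, min((w + 1) * per_win, n))
        v = valid[sl]
        frac = float(v.mean()) if v.size else 0.0
        odba = float(l1[sl][v].mean()) if frac >= min_valid_frac and v.any() else np.nan
        rows.append({"minute_index": w, "odba_raw": odba, "valid_fraction": frac})
    return pd.DataFrame(rows)


def normalize_odba(series: pd.DataFrame, across: str = "median_of_medians"
                   ) -> pd.DataFrame:
    """Median-normalize ODBA across individuals.

    Each individual's minutes are divided by that individual's median and
    multiplied by a common reference median M, so every individual ends with
    median exactly M while within-individual rank order is preserved.
    ``across`` selects M: the median of the individual medians (default) or
    the median of all pooled minutes (``"pooled"``).

    Parameters
    ----------
    series : DataFrame with ``individual_id`` and ``odba_raw`` columns
        (NaN minutes ignored).

    Returns a copy with an ``odba_norm`` column added.
    """
    if "individual_id" not in series or "odba_raw" not in series:
        raise ValueError("series needs individual_id and odba_raw columns")
    medians = series.groupby("individual_id")["odba_raw"].median()
    if medians.isna().any() or medians.empty:
        raise ValueError("every individual needs at least one valid minute")
    if across == "median_of_medians":
        ref = float(medians.median())
    elif across == "pooled":
        ref = float(series["odba_raw"].median())
    else:
        raise ValueError(f"unknown across mode {across!r}")
    out = series.copy()
    out["odba_norm"] = (
        out["odba_raw"] / out["individual_id"].map(medians).astype(float) * ref
    )
    return out


def trim_deployment(dives: pd.DataFrame, first_window_s: float = 3600.0
                    ) -> pd.DataFrame:
    """Apply deployment trimming rules to a chronologically ordered dive table.

    Drops every dive starting before the later of (a) the end of the first
    dive cycle (its ``surface_end_s``, falling back to ``end_s``) and (b)
    ``first_window_s`` (default 1 h) — tag-reaction conditioning.  Also
    drops the final dive when its ``truncated`` flag is set (tag detached
    mid-dive).
    """
    if dives.empty:
        return dives.copy()
    start = dives["start_s"].to_numpy()
    if np.any(np.diff(start) < 0):
        raise ValueError("dive table must be chronologically ordered")
    first = dives.iloc[0]
    cycle_end = float(first.get("surface_end_s", first["end_s"]))
    if np.isnan(cycle_end):
        cycle_end = float(first["end_s"])
    cut = max(cycle_end, first_window_s)
    out = dives[dives["start_s"] >= cut]
    if len(out) and "truncated" in out.columns and bool(out.iloc[-1]["truncated"]):
        out = out.iloc[:-1]
    return out.reset_index(drop=True)


def odba_from_record(
    record: TriaxialRecord,
    gate_angle_deg: float = DEFAULT_GATE_ANGLE_DEG,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    window_s: float = 60.0,
    min_valid_frac: float = 0.5,
) -> pd.DataFrame:
    """Full per-record pipeline: DA -> SA -> minute ODBA.

    Returns the ``odba_minutely`` frame with the record's ``individual_id``
    attached (ready for ``normalize_odba``).
    """
    da = highpass(record.acc, record.fs, highpass_hz)
    static = record.acc - da
    sa, valid = specific_acceleration(
        da, record.mag, static, record.fs,
        gate_angle_deg=gate_angle_deg, highpass_hz=highpass_hz)
    out = odba_minutely(sa, valid, record.fs, window_s, min_valid_frac)
    out["individual_id"] = record.individual_id
    return out
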