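"""ODBA signal processing: filtering, rotation removal, windowing, trimming."""

import numpy as np
import pandas as pd
import pytest

from whalefmr.odba import (
    DEFAULT_HIGHPASS_HZ,
    FLUKING_HZ,
    TriaxialRecord,
    highpass,
    normalize_odba,
    odba_from_record,
    odba_minutely,
    specific_acceleration,
    trim_deployment,
)

FS = 25.0


def _t(seconds=600.0, fs=FS):
    return np.arange(0, seconds, 1 / fs)


class TestHighpass:
    def test_default_cutoff_is_04x_fluking(self):
        assert DEFAULT_HIGHPASS_HZ == pytest.approx(0.4 * FLUKING_HZ)
        assert DEFAULT_HIGHPASS_HZ == pytest.approx(0.068)

    def test_static_component_rejected(self):
        x = np.full((int(600 * FS), 3), 9.81)
        y = highpass(x, FS)
        assert np.abs(y).max() < 0.01 * 9.81

    @pytest.mark.parametrize("freq, min_gain", [
        (FLUKING_HZ, 0.95),  # fluking band must pass
        (0.5, 0.95),         # stroke harmonics too
    ])
    def test_passband_gain(self, freq, min_gain):
        t = _t()
        x = np.sin(2 * np.pi * freq * t)[:, None] * np.ones(3)
        y = highpass(x, FS)
        core = slice(int(60 * FS), int(540 * FS))  # skip filter edges
        gain = np.abs(y[core, 0]).max() / 1.0
        assert gain > min_gain
        assert gain < 1.05

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.zeros((100, 3)), fs=25.0, cutoff=13.0)

    def test_deterministic(self):
        x = np.random.default_rng(0).normal(size=(1000, 3))
        assert np.array_equal(highpass(x, FS), highpass(x, FS))


def _rotation_stream(amp_rad=0.12, seconds=600.0, field=(30.0, 5.0, -20.0)):
    """Pure pitch oscillation about the lateral axis: gravity and the
    magnetic field sweep through the body frame, with zero true SA."""
    t = _t(seconds)
    phi = amp_rad * np.sin(2 * np.pi * FLUKING_HZ * t)
    g = 9.81
    acc = np.column_stack([-g * np.sin(phi), np.zeros_like(t), g * np.cos(phi)])
    ux, uy, uz = field
    mag = np.column_stack([
        ux * np.cos(phi) - uz * np.sin(phi),
        np.full_like(t, uy),
        ux * np.sin(phi) + uz * np.cos(phi),
    ])
    return acc, mag


class TestSpecificAcceleration:
    def test_pure_linear_oscillation_passes_unchanged(self):
        t = _t()
        amp = 0.5
        acc = np.zeros((t.size, 3))
        acc[:, 2] = 9.81
        acc[:, 0] = amp * np.sin(2 * np.pi * FLUKING_HZ * t)
        mag = np.tile([30.0, 5.0, -20.0], (t.size, 1))
        da = highpass(acc, FS)
        sa, valid = specific_acceleration(da, mag, acc - da, FS)
        assert valid.all()
        assert np.abs(sa - da).max() / amp < 0.05

    def test_pure_rotation_suppressed(self):
        acc, mag = _rotation_stream()
        da = highpass(acc, FS)
        sa, valid = specific_acceleration(da, mag, acc - da, FS)
        core = slice(int(60 * FS), -int(60 * FS))
        assert np.abs(sa[core]).max() < 0.10 * np.abs(da[core]).max()

    def test_field_aligned_with_rotation_axis_gated(self):
        acc, _ = _rotation_stream()
        # field within 25 degrees of the lateral (y) axis
        mag = np.tile([1.0, 30.0, 1.0], (acc.shape[0], 1))
        da = highpass(acc, FS)
        _, valid = specific_acceleration(da, mag, acc - da, FS)
        assert not valid.any()

    def test_zero_norm_field_flagged_invalid(self):
        acc, mag = _rotation_stream()
        mag[100:200] = 0.0
        da = highpass(acc, FS)
        _, valid = specific_acceleration(da, mag, acc - da, FS)
        assert not valid[100:200].any()
        assert valid[300:].all()

    def test_deterministic(self):
        acc, mag = _rotation_stream()
        da = highpass(acc, FS)
        sa1, _ = specific_acceleration(da, mag, acc - da, FS)
        sa2, _ = specific_acceleration(da, mag, acc - da, FS)
        assert np.array_equal(sa1, sa2)


class TestOdbaMinutely:
    def test_constant_sa_gives_l1(self):
        sa = np.full((int(120 * FS), 3), 0.2)
        out = odba_minutely(sa, fs=FS)
        assert out["odba_raw"].iloc[0] == pytest.approx(3 * 0.2)

    def test_sinusoid_mean_absolute_value(self):
        """Mean |A sin| over full cycles is (2/pi) A."""
        t = _t(300.0)
        sa = np.zeros((t.size, 3))
        amp = 0.7
        sa[:, 0] = amp * np.sin(2 * np.pi * 0.2 * t)
        out = odba_minutely(sa, fs=FS)
        assert out["odba_raw"].iloc[2] == pytest.approx(2 / np.pi * amp, rel=0.05)

    def test_fully_masked_window_is_missing_not_zero(self):
        sa = np.ones((int(120 * FS), 3))
        valid = np.ones(sa.shape[0], dtype=bool)
        valid[: int(60 * FS)] = False
        out = odba_minutely(sa, valid, fs=FS)
        assert np.isnan(out["odba_raw"].iloc[0])
        assert out["odba_raw"].iloc[1] == pytest.approx(3.0)

    def test_low_valid_fraction_window_dropped(self):
        sa = np.ones((int(60 * FS), 3))
        valid = np.zeros(sa.shape[0], dtype=bool)
        valid[: int(20 * FS)] = True  # 1/3 valid < 0.5 floor
        out = odba_minutely(sa, valid, fs=FS, min_valid_frac=0.5)
        assert np.isnan(out["odba_raw"].iloc[0])


class TestNormalizeOdba:
    @staticmethod
    def _series(meds):
        frames = []
        rng = np.random.default_rng(0)
        for ind, med in meds.items():
            frames.append(pd.DataFrame({
                "individual_id": ind,
                "odba_raw": med * rng.uniform(0.5, 1.5, 101),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_single_individual_is_identity(self):
        s = self._series({"a": 0.1})
        out = normalize_odba(s)
        assert np.allclose(out["odba_norm"], out["odba_raw"])

    def test_two_individuals_equalized_to_common_median(self):
        s = self._series({"a": 0.05, "b": 0.15})
        out = normalize_odba(s)
        med = out.groupby("individual_id")["odba_norm"].median()
        assert med["a"] == pytest.approx(med["b"])

    def test_rank_order_preserved(self):
        s = self._series({"a": 0.05, "b": 0.15})
        out = normalize_odba(s)
        for _, g in out.groupby("individual_id"):
            assert np.array_equal(np.argsort(g["odba_raw"].to_numpy()),
                                  np.argsort(g["odba_norm"].to_numpy()))

    def test_idempotent(self):
        s = self._series({"a": 0.05, "b": 0.15, "c": 0.4})
        once = normalize_odba(s)
        twice = normalize_odba(
            once.drop(columns="odba_raw").rename(columns={"odba_norm": "odba_raw"}))
        assert np.allclose(once["odba_norm"], twice["odba_norm"])


def _dive_table(starts_min, dur_min=45.0, surf_min=9.0, truncated_last=False):
    rows = []
    for i, s in enumerate(starts_min):
        rows.append({
            "dive_id": i,
            "start_s": s * 60.0,
            "end_s": (s + dur_min) * 60.0,
            "surface_end_s": (s + dur_min + surf_min) * 60.0,
            "truncated": truncated_last and i == len(starts_min) - 1,
        })
    return pd.DataFrame(rows)


class TestTrimDeployment:
    def test_first_cycle_and_first_hour_both_dropped(self):
        # cycle 1 ends at 54 min; dive 2 starts at 54 min < 60 min -> dropped too
        dives = _dive_table([0, 54, 108, 162])
        out = trim_deployment(dives)
        assert list(out["dive_id"]) == [2, 3]

    def test_long_first_cycle_only_cycle_dropped(self):
        dives = _dive_table([0, 70, 140], dur_min=61.0)
        out = trim_deployment(dives)
        assert list(out["dive_id"]) == [1, 2]

    def test_truncated_last_dive_dropped(self):
        dives = _dive_table([0, 70, 140], truncated_last=True)
        out = trim_deployment(dives)
        assert list(out["dive_id"]) == [1]

    def test_unordered_rejected(self):
        dives = _dive_table([70, 0])
        with pytest.raises(ValueError):
            trim_deployment(dives)


def test_end_to_end_fluking_oracle(tmp_path):
    """Gravity + one-axis fluking sinusoid with no rotation: the full
    record pipeline must recover minute ODBA = (2/pi) * amplitude."""
    fs = 25.0
    t = np.arange(0, 300, 1 / fs)
    amp = 0.4
    acc = np.zeros((t.size, 3))
    acc[:, 2] = 9.81
    acc[:, 0] = amp * np.sin(2 * np.pi * FLUKING_HZ * t)
    mag = np.tile([30.0, 5.0, -20.0], (t.size, 1))
    rec = TriaxialRecord(t=t, acc=acc, mag=mag, depth=np.zeros(t.size),
                         fs=fs, individual_id="sw01")
    out = odba_from_record(rec)
    assert out["odba_raw"].iloc[2] == pytest.approx(2 / np.pi * amp, rel=0.05)


def test_record_csv_round_trip(tmp_path):
    t = np.arange(0, 10, 0.1)
    rng = np.random.default_rng(1)
    rec = TriaxialRecord(t=t, acc=rng.normal(size=(t.size, 3)),
                         mag=rng.normal(size=(t.size, 3)),
                         depth=np.abs(rng.normal(size=t.size)),
                         fs=10.0, individual_id="sw07")
    df = pd.DataFrame({
        "t_s": rec.t,
        "ax": rec.acc[:, 0], "ay": rec.acc[:, 1], "az": rec.acc[:, 2],
        "mx": rec.mag[:, 0], "my": rec.mag[:, 1], "mz": rec.mag[:, 2],
        "depth_m": rec.depth,
    })
    df.to_csv(tmp_path / "s.csv", index=False)
    (tmp_path / "s.json").write_text(
        '{"fs_hz": 10.0, "units": "m/s^2", "individual_id": "sw07"}')
    back = TriaxialRecord.from_csv(tmp_path / "s.csv")
    assert back.fs == 10.0 and back.individual_id == "sw07"
    assert np.allclose(back.acc, rec.acc)
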