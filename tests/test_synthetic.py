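"""Synthetic tag generator: statistical structure and round-trip recovery."""

import numpy as np
import pytest

from whalefmr.odba import highpass, odba_minutely, specific_acceleration, trim_deployment
from whalefmr.respiration import segment_surface_table
from whalefmr.synthetic import (
    generate_dive_table,
    generate_respiration_events,
    generate_sensor_stream,
    generate_tag_dataset,
    surface_table,
    time_budget,
)

DAY_S = 24 * 3600.0


class TestDiveTable:
    def test_daily_time_budget(self, tag_config, rng):
        """A 24-h deployment splits ~60/10/30 between diving, post-dive
        surfacing and non-foraging surface time."""
        dives = generate_dive_table(tag_config, rng, deployment_s=DAY_S)
        budget = time_budget(dives, DAY_S)
        assert budget["diving"] == pytest.approx(0.60, abs=0.05)
        assert budget["postdive"] == pytest.approx(0.10, abs=0.05)
        assert budget["nonforaging"] == pytest.approx(0.30, abs=0.08)

    def test_mean_postdive_surfacing_near_9_min(self, tag_config):
        durs = []
        for seed in range(5):
            dives = generate_dive_table(tag_config, seed, deployment_s=DAY_S)
            st = surface_table(dives)
            surf_min = (st["end_s"] - st["start_s"]) / 60.0
            durs.extend(surf_min.clip(upper=9.0 + 3).tolist())
        # the recovery part of each surfacing (long blocks excluded)
        core = [d for d in durs if d < 12]
        assert np.mean(core) == pytest.approx(9.0, abs=1.0)

    def test_truncated_flag_when_deployment_ends_mid_dive(self, tag_config):
        # a deployment far shorter than one dive always ends mid-dive
        dives = generate_dive_table(tag_config, 0, deployment_s=600.0)
        assert len(dives) == 1 and bool(dives["truncated"].iloc[0])

    def test_short_deployment_empty_after_trim(self, tag_config):
        dives = generate_dive_table(tag_config, 1, deployment_s=600.0)
        assert trim_deployment(dives).empty

    def test_chronological_and_consistent(self, tag_config, rng):
        d = generate_dive_table(tag_config, rng, deployment_s=DAY_S)
        assert (d["start_s"] <= d["descent_end_s"]).all()
        assert (d["descent_end_s"] <= d["bottom_end_s"]).all()
        assert (d["bottom_end_s"] <= d["end_s"]).all()
        assert (d["end_s"] <= d["surface_end_s"]).all()
        assert np.all(np.diff(d["start_s"]) > 0)


class TestRespirationEvents:
    def test_rates_recover_period_means(self, tag_config):
        """Pooled empirical breath rates per period match the generating
        respiration-rate means within sampling error."""
        rng = np.random.default_rng(5)
        counts = {1: 0, 2: 0, 3: 0}
        minutes = {1: 0.0, 2: 0.0, 3: 0.0}
        for _ in range(6):
            dives = generate_dive_table(tag_config, rng, deployment_s=DAY_S)
            segs = segment_surface_table(surface_table(dives))
            ev = generate_respiration_events(segs, rng=rng)
            for pid in counts:
                counts[pid] += int((ev["period_id"] == pid).sum())
                sel = segs["period_id"] == pid
                minutes[pid] += float((segs["end_s"] - segs["start_s"])[sel].sum()) / 60.0
        for pid, target in ((1, 5.06), (2, 3.50), (3, 1.37)):
            rate = counts[pid] / minutes[pid]
            se = np.sqrt(counts[pid]) / minutes[pid]
            assert abs(rate - target) < 3 * se

    def test_expected_count_short_segment(self, tag_config):
        """A 7.2-min period-1 segment at 5.06 breaths/min carries ~36 events."""
        import pandas as pd
        seg = pd.DataFrame({"start_s": [0.0], "end_s": [432.0], "period_id": [1]})
        n = np.mean([len(generate_respiration_events(seg, rng=s))
                     for s in range(200)])
        assert n == pytest.approx(5.06 * 7.2, rel=0.1)

    def test_zero_duration_segment_no_events(self, tag_config):
        import pandas as pd
        seg = pd.DataFrame({"start_s": [10.0], "end_s": [10.0], "period_id": [1]})
        assert generate_respiration_events(seg, rng=0).empty


class TestSensorStream:
    def test_row_count_matches_rate(self, tag_config, rng):
        dives = generate_dive_table(tag_config, rng, deployment_s=3600.0)
        stream = generate_sensor_stream(dives, tag_config, rng, deployment_s=3600.0)
        assert len(stream) == int(3600 * tag_config.fs_hz)

    def test_bottom_phase_odba_exceeds_surface(self, tag_config, rng):
        """Fluking amplitude is higher at the bottom phase by construction,
        so recovered minute ODBA must be too."""
        dives = generate_dive_table(tag_config, rng, deployment_s=2 * 3600.0)
        stream = generate_sensor_stream(dives, tag_config, rng,
                                        deployment_s=2 * 3600.0)
        acc = stream[["ax", "ay", "az"]].to_numpy()
        mag = stream[["mx", "my", "mz"]].to_numpy()
        da = highpass(acc, tag_config.fs_hz)
        sa, valid = specific_acceleration(da, mag, acc - da, tag_config.fs_hz)
        om = odba_minutely(sa, valid, tag_config.fs_hz)
        phase_per_min = stream["phase"].iloc[::int(60 * tag_config.fs_hz)].to_numpy()
        phase_per_min = phase_per_min[: len(om)]
        bottom = om["odba_raw"][phase_per_min == "bottom"].dropna()
        surface = om["odba_raw"][phase_per_min == "surface"].dropna()
        assert bottom.mean() > surface.mean()

    def test_end_to_end_odba_recovery(self, tag_config, rng):
        """Deployment-mean recovered ODBA agrees with the ground-truth
        specific-acceleration L1 mean within 10%."""
        dives = generate_dive_table(tag_config, rng, deployment_s=2 * 3600.0)
        stream = generate_sensor_stream(dives, tag_config, rng,
                                        deployment_s=2 * 3600.0)
        acc = stream[["ax", "ay", "az"]].to_numpy()
        mag = stream[["mx", "my", "mz"]].to_numpy()
        da = highpass(acc, tag_config.fs_hz)
        sa, valid = specific_acceleration(da, mag, acc - da, tag_config.fs_hz)
        om = odba_minutely(sa, valid, tag_config.fs_hz)
        truth = odba_minutely(stream[["sa_x", "sa_y", "sa_z"]].to_numpy(),
                              None, tag_config.fs_hz)
        m = om["odba_raw"].notna() & truth["odba_raw"].notna()
        rel = om["odba_raw"][m].mean() / truth["odba_raw"][m].mean() - 1.0
        assert abs(rel) < 0.10

    def test_depth_consistent_with_phases(self, tag_config, rng):
        dives = generate_dive_table(tag_config, rng, deployment_s=3600.0)
        stream = generate_sensor_stream(dives, tag_config, rng, deployment_s=3600.0)
        bottom = stream.loc[stream["phase"] == "bottom", "depth_m"]
        surface = stream.loc[stream["phase"] == "surface", "depth_m"]
        assert bottom.min() > 700.0
        assert surface.max() < 10.0


def test_dataset_writer_round_trip(tmp_path, tag_config):
    tag_config.n_individuals = 2
    tag_config.deployment_hours_range = (0.5, 1.0)
    manifest = generate_tag_dataset(tag_config, tmp_path, seed=3)
    assert len(manifest["individuals"]) == 2
    for ind, files in manifest["individuals"].items():
        for key in ("dive_table", "breaths", "sensors"):
            assert (tmp_path / files[key]).exists()
    assert (tmp_path / "manifest.json").exists()
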