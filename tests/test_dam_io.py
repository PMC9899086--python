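"""Monitor-file parsing, minute binning and day/phase annotation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sleepscreen as ss
from sleepscreen.dam_io import (
    DamParseError,
    DamValidationError,
    ExperimentDesign,
    MonitorReading,
    filter_dead_flies,
)

T0 = dt.datetime(2024, 1, 1, 8, 0, 0)


def make_reading(minute_offset, counts=None, status=1, seconds=0):
    c = [0] * 32 if counts is None else counts
    return MonitorReading(
        T0 + dt.timedelta(minutes=minute_offset, seconds=seconds),
        status,
        tuple(c),
        index=minute_offset + 1,
    )


def three_day_design(lights_on=dt.time(8, 0)):
    d0 = dt.date(2024, 1, 1)
    return ExperimentDesign(
        lights_on=lights_on,
        day_roles={
            d0: "baseline",
            d0 + dt.timedelta(days=1): "activation",
            d0 + dt.timedelta(days=2): "recovery",
        },
    )


class TestReadWrite:
    def test_round_trip_preserves_every_field(self, tmp_path):
        readings = [
            make_reading(i, counts=[(i + j) % 7 for j in range(32)]) for i in range(3)
        ]
        path = tmp_path / "m.txt"
        ss.write_dam_monitor(readings, path)
        back = ss.read_dam_monitor(path)
        assert back == readings

    def test_canonical_round_trip_is_byte_identical(self, tmp_path, rng):
        readings = [
            make_reading(i, counts=list(rng.integers(0, 50, 32))) for i in range(100)
        ]
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        ss.write_dam_monitor(readings, p1)
        ss.write_dam_monitor(ss.read_dam_monitor(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_wrong_column_count_names_the_line(self, tmp_path):
        path = tmp_path / "m.txt"
        good = "\t".join(["1", "1 Jan 24", "08:00:00", "1"] + ["0"] * 6 + ["0"] * 32)
        bad = "\t".join(["2", "1 Jan 24", "08:01:00", "1"] + ["0"] * 6 + ["0"] * 30)
        path.write_text(good + "\n" + bad + "\n")
        with pytest.raises(DamParseError, match="line 2"):
            ss.read_dam_monitor(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        readings = [make_reading(0), make_reading(2), make_reading(1)]
        path = tmp_path / "m.txt"
        ss.write_dam_monitor(readings, path)
        with pytest.raises(DamValidationError, match="line 3"):
            ss.read_dam_monitor(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ss.read_dam_monitor(tmp_path / "nope.txt")

    def test_three_day_file_reads_back_in_order(self, tmp_path, small_screen):
        """A simulator-written 4320-row file re-reads with strictly increasing stamps."""
        paths = ss.write_screen(small_screen, tmp_path)
        readings = ss.read_dam_monitor(next(iter(paths.values())))
        assert len(readings) == 4320
        stamps = [r.timestamp for r in readings]
        assert all(a < b for a, b in zip(stamps, stamps[1:]))
        col = np.array([r.channel_counts[0] for r in readings])
        assert np.array_equal(col, small_screen.counts[0])


class TestBinToMinutes:
    def test_sub_minute_readings_sum_into_the_minute(self):
        r1 = make_reading(0, counts=[2] + [0] * 31, seconds=0)
        r2 = make_reading(0, counts=[3] + [0] * 31, seconds=30)
        out = ss.bin_to_minutes([r1, r2], channel=1)
        assert out.iloc[0] == 5

    def test_one_minute_cadence_is_identity(self, rng):
        counts = rng.integers(0, 10, 30)
        readings = [make_reading(i, counts=[int(c)] + [0] * 31) for i, c in enumerate(counts)]
        out = ss.bin_to_minutes(readings, channel=1)
        assert np.array_equal(out.to_numpy(), counts)

    def test_ten_second_cadence_matches_brute_force_sums(self, rng):
        per_read = rng.integers(0, 4, 30)  # 5 minutes at 6 readings/min
        readings = [
            make_reading(i // 6, counts=[int(per_read[i])] + [0] * 31, seconds=10 * (i % 6))
            for i in range(30)
        ]
        out = ss.bin_to_minutes(readings, channel=1)
        expected = [int(per_read[6 * m:6 * (m + 1)].sum()) for m in range(5)]
        assert out.tolist() == expected

    def test_gap_minutes_are_missing_not_zero(self):
        readings = [make_reading(0, counts=[1] + [0] * 31), make_reading(2, counts=[1] + [0] * 31)]
        out = ss.bin_to_minutes(readings, channel=1)
        assert len(out) == 3 and np.isnan(out.iloc[1])

    def test_invalid_status_minute_is_missing(self):
        readings = [make_reading(0, counts=[5] + [0] * 31, status=51)]
        out = ss.bin_to_minutes(readings, channel=1)
        assert np.isnan(out.iloc[0])

    def test_channel_out_of_range(self):
        with pytest.raises(ValueError, match="channel"):
            ss.bin_to_minutes([make_reading(0)], channel=33)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=120))
    def test_sum_conservation(self, counts):
        readings = [
            make_reading(i // 2, counts=[c] + [0] * 31, seconds=30 * (i % 2))
            for i, c in enumerate(counts)
        ]
        out = ss.bin_to_minutes(readings, channel=1)
        assert out.sum() == sum(counts)


class TestAnnotate:
    def _series(self, start, n):
        idx = pd.date_range(start, periods=n, freq="min")
        return pd.Series(np.ones(n), index=idx)

    def test_minute_before_lights_on_is_dp_of_that_calendar_day(self):
        s = self._series(dt.datetime(2024, 1, 2, 7, 59), 1)
        fas = ss.annotate(s, three_day_design(), fly_id="f", genotype="g",
                          driver=None, genotype_role="experimental")
        row = fas.data.iloc[0]
        assert (row["phase"], row["day_role"], row["zt_minute"]) == ("DP", "activation", 1439)

    def test_lights_on_minute_is_zt_zero_lp(self):
        s = self._series(dt.datetime(2024, 1, 2, 8, 0), 1)
        fas = ss.annotate(s, three_day_design(), fly_id="f", genotype="g",
                          driver=None, genotype_role="experimental")
        row = fas.data.iloc[0]
        assert (row["phase"], row["day_role"], row["zt_minute"]) == ("LP", "activation", 0)

    def test_full_three_days_partition_into_720_lp_720_dp_each(self):
        s = self._series(dt.datetime(2024, 1, 1, 0, 0), 3 * 1440)
        fas = ss.annotate(s, three_day_design(), fly_id="f", genotype="g",
                          driver=None, genotype_role="experimental")
        sizes = fas.data.groupby(["day_role", "phase"]).size()
        assert set(sizes) == {720}
        assert len(sizes) == 6

    def test_minutes_outside_design_days_dropped(self):
        s = self._series(dt.datetime(2023, 12, 31, 23, 58), 4)
        fas = ss.annotate(s, three_day_design(), fly_id="f", genotype="g",
                          driver=None, genotype_role="experimental")
        assert len(fas.data) == 2  # only the two minutes on Jan 1

    def test_design_requires_all_three_roles(self):
        with pytest.raises(ValueError, match="day_roles"):
            ExperimentDesign(
                lights_on=dt.time(8, 0),
                day_roles={dt.date(2024, 1, 1): "baseline", dt.date(2024, 1, 2): "activation"},
            )

    def test_design_yaml_round_trip(self, tmp_path):
        design = three_day_design()
        design.to_yaml(tmp_path / "d.yaml")
        back = ExperimentDesign.from_yaml(tmp_path / "d.yaml")
        assert back.lights_on == design.lights_on
        assert back.day_roles == design.day_roles


class TestDeadFlyFilter:
    def _fly(self, recovery_counts):
        n = len(recovery_counts)
        data = pd.DataFrame(
            {
                "date": [dt.date(2024, 1, 3)] * n,
                "zt_minute": range(n),
                "day_role": ["recovery"] * n,
                "phase": ["LP"] * n,
                "count": recovery_counts,
            }
        )
        return ss.FlyActivitySeries("f1", "g", None, "experimental", data)

    def test_all_zero_recovery_day_dropped(self):
        d = filter_dead_flies(self._fly([0.0] * 60), min_active_minutes_last_day=1)
        assert not d.keep and "dropped" in d.reason

    def test_threshold_zero_keeps_everything(self):
        d = filter_dead_flies(self._fly([0.0] * 60), min_active_minutes_last_day=0)
        assert d.keep

    def test_five_active_minutes_below_threshold_ten(self):
        counts = [0.0] * 60
        for i in (3, 10, 20, 30, 40):
            counts[i] = 2.0
        d = filter_dead_flies(self._fly(counts), min_active_minutes_last_day=10)
        assert not d.keep and d.active_minutes_last_day == 5
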