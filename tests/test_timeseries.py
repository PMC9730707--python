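import numpy as np
import pandas as pd
import pytest

from lysiphen.errors import AlignmentError, EmptyInputError, FormatError
from lysiphen.timeseries import (
    EnvSeries,
    WeightSeries,
    align_to_grid,
    detect_irrigation_events,
    read_weight_series,
    write_weight_series,
)

from conftest import make_weight_frame


def _write(tmp_path, text, name="w.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWeightSeries:
    def test_well_formed_rows_all_parsed(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,weight_g\n"
            "2022-04-01T00:00:00,1000.0\n"
            "2022-04-01T00:03:00,999.5\n"
            "2022-04-01T00:06:00,999.0\n",
        )
        ws = read_weight_series(p, "potA")
        assert len(ws) == 3
        assert ws.parse_report.n_dropped == 0
        assert len(ws.gaps()) == 0

    def test_malformed_timestamp_dropped_and_counted(self, tmp_path):
        rows = [f"2022-04-01T00:{3 * i:02d}:00,{1000 - i}" for i in range(10)]
        rows[4] = "not-a-time,996"
        p = _write(tmp_path, "timestamp,weight_g\n" + "\n".join(rows) + "\n")
        ws = read_weight_series(p, "potA")
        assert len(ws) == 9
        assert ws.parse_report.n_dropped_timestamp == 1

    def test_non_numeric_weight_dropped(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,weight_g\n2022-04-01T00:00:00,abc\n2022-04-01T00:03:00,10\n",
        )
        ws = read_weight_series(p, "potA")
        assert len(ws) == 1
        assert ws.parse_report.n_dropped_value == 1

    def test_missing_weight_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "timestamp,mass\n2022-04-01T00:00:00,10\n")
        with pytest.raises(FormatError):
            read_weight_series(p, "potA")

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        p = _write(tmp_path, "timestamp,weight_g\nbad,worse\n")
        with pytest.raises(EmptyInputError):
            read_weight_series(p, "potA")

    def test_round_trip_is_bit_exact(self, tmp_path):
        weights = [1000.1, 999.95 + 0.1 + 0.2, 998.123456789012345, 0.0]
        ws = WeightSeries("potA", make_weight_frame("2022-04-01", weights))
        out = tmp_path / "rt.csv"
        write_weight_series(ws, out)
        back = read_weight_series(out, "potA")
        assert np.array_equal(back.weight.to_numpy(), ws.weight.to_numpy())
        assert back.timestamps.equals(ws.timestamps)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            WeightSeries("p", make_weight_frame("2022-04-01", [1.0, -2.0]))
        frame = make_weight_frame("2022-04-01", [1.0, 2.0])
        frame.index = pd.DatetimeIndex(["2022-04-01", "2022-04-01"])
        with pytest.raises(ValueError):
            WeightSeries("p", frame)


class TestDetectIrrigationEvents:
    def test_monotone_decrease_yields_no_flags(self):
        ws = WeightSeries("p", make_weight_frame("2022-04-01", np.linspace(1000, 900, 50)))
        assert detect_irrigation_events(ws, 5.0).irrigation_flag.sum() == 0

    def test_four_nightly_pulses_flagged_exactly(self):
        w = list(np.linspace(1000, 990, 20))
        for _ in range(4):  # four +50 g pulses separated by decline
            w += [w[-1] + 50.0]
            w += list(np.linspace(w[-1] - 0.5, w[-1] - 5.0, 10))
        ws = WeightSeries("p", make_weight_frame("2022-04-01", w))
        flagged = detect_irrigation_events(ws, 5.0)
        assert flagged.irrigation_flag.sum() == 4

    def test_threshold_dominating_every_jump(self):
        w = [100, 102, 101, 103, 102]
        ws = WeightSeries("p", make_weight_frame("2022-04-01", w))
        assert detect_irrigation_events(ws, 5.0).irrigation_flag.sum() == 0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        w = np.abs(np.cumsum(rng.normal(0, 3, 100)) + 500)
        ws = WeightSeries("p", make_weight_frame("2022-04-01", w))
        f1 = detect_irrigation_events(ws, 4.0).irrigation_flag
        f2 = detect_irrigation_events(ws, 4.0).irrigation_flag
        assert f1.equals(f2)


def _env_frame(start, n, step="3min", **cols):
    idx = pd.date_range(start, periods=n, freq=step)
    base = {"t_air_c": 20.0, "rh_pct": 60.0, "par_umol": 100.0, "vwc": 0.25}
    base.update(cols)
    return EnvSeries(frame=pd.DataFrame(base, index=idx))


class TestAlignToGrid:
    def test_identical_timestamps_preserved(self):
        ws = WeightSeries("p", make_weight_frame("2022-04-01", np.linspace(1000, 990, 40)))
        env = _env_frame("2022-04-01", 40)
        out = align_to_grid(ws, env)
        assert len(out) == 40
        assert set(["weight_g", "t_air_c", "rh_pct", "par_umol", "vwc"]) <= set(out.columns)

    def test_one_minute_offset_pairs_nearest(self):
        ws = WeightSeries("p", make_weight_frame("2022-04-01 00:03:00", [10, 9, 8, 7]))
        env = _env_frame("2022-04-01 00:04:00", 4)
        out = align_to_grid(ws, env)
        assert len(out) == 4  # each weight row pairs with the +1 min env row

    def test_disjoint_ranges_raise(self):
        ws = WeightSeries("p", make_weight_frame("2022-04-01", [10, 9, 8]))
        env = _env_frame("2022-05-01", 3)
        with pytest.raises(AlignmentError):
            align_to_grid(ws, env)

    def test_output_bounded_by_overlap_and_lengths(self):
        ws = WeightSeries("p", make_weight_frame("2022-04-01 00:00:00", np.linspace(50, 40, 100)))
        env = _env_frame("2022-04-01 01:00:00", 10)
        out = align_to_grid(ws, env)
        assert len(out) <= min(len(ws), len(env))
        assert out.index.min() >= env.frame.index[0] - pd.Timedelta("90s")
        assert out.index.max() <= env.frame.index[-1] + pd.Timedelta("90s")

    def test_env_validation(self):
        with pytest.raises(ValueError):
            _env_frame("2022-04-01", 3, rh_pct=150.0)
        with pytest.raises(ValueError):
            _env_frame("2022-04-01", 3, vwc=1.5)
        idx = pd.date_range("2022-04-01", periods=3, freq="3min")
        with pytest.raises(FormatError):
            EnvSeries(frame=pd.DataFrame({"t_air_c": 20.0}, index=idx))
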