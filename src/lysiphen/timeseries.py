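"""Reading, validation and alignment of the gravimetric and sensor streams.

A multi-pot gravimetric phenotyping array records each pot's total system
weight (pot + substrate + water + plant) on a nominal 3-minute cadence, while
shared sensors log air temperature, relative humidity and PAR, and per-pot
probes log volumetric soil water content (VWC). This module parses those
streams from delimited text, validates their invariants (strictly increasing
timestamps, finite non-negative weights, RH in [0,100], VWC in [0,1]), flags
irrigation pulses from upward weight jumps and joins the two streams on a
common grid by nearest-neighbor matching.

Timestamps are ISO-8601 local clock time, timezone-naive: the analysis windows
are defined by greenhouse clock hours, and a single-site experiment needs no
daylight-saving arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError, FormatError

__all__ = [
    "ParseReport",
    "WeightSeries",
    "EnvSeries",
    "read_weight_series",
    "write_weight_series",
    "read_env_series",
    "write_env_series",
    "detect_irrigation_events",
    "align_to_grid",
]

#: Nominal sampling cadence of the platform.
NOMINAL_STEP = pd.Timedelta("3min")

#: Default upward weight jump (g per interval) treated as an irrigation pulse.
DEFAULT_JUMP_THRESHOLD = 5.0

#: Longest gap (3 missed samples) across which streams may still be joined.
DEFAULT_MAX_GAP = pd.Timedelta("9min")

ENV_COLUMNS = ("t_air_c", "rh_pct", "par_umol")


@dataclass
class ParseReport:
    """Row accounting from parsing one delimited input file."""

    path: str
    n_rows: int = 0
    n_dropped_timestamp: int = 0
    n_dropped_value: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_timestamp + self.n_dropped_value

    @property
    def n_valid(self) -> int:
        return self.n_rows - self.n_dropped

    def to_text(self) -> str:
        return (
            f"file: {self.path}\n"
            f"rows: {self.n_rows}\n"
            f"dropped_unparseable_timestamp: {self.n_dropped_timestamp}\n"
            f"dropped_non_numeric_value: {self.n_dropped_value}\n"
            f"valid: {self.n_valid}\n"
        )


def _validate_index(index: pd.DatetimeIndex, what: str) -> None:
    if len(index) and not index.is_monotonic_increasing:
        raise ValueError(f"{what}: timestamps must be increasing")
    if len(index) and index.has_duplicates:
        raise ValueError(f"{what}: timestamps must be strictly increasing (duplicates found)")


@dataclass(eq=False)
class WeightSeries:
    """One pot's timestamped system weight (g) with irrigation-event flags.

    ``frame`` is indexed by a strictly increasing DatetimeIndex and holds the
    columns ``weight_g`` (finite, >= 0) and ``irrigation_flag`` (bool; an
    instant is flagged when the interval ending at it was an irrigation pulse).
    """

    pot_id: str
    frame: pd.DataFrame
    parse_report: ParseReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise TypeError("WeightSeries.frame must have a DatetimeIndex")
        _validate_index(f.index, f"WeightSeries({self.pot_id})")
        if "weight_g" not in f.columns:
            raise FormatError("WeightSeries.frame must have a 'weight_g' column")
        w = f["weight_g"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        if "irrigation_flag" not in f.columns:
            f["irrigation_flag"] = False
        f["irrigation_flag"] = f["irrigation_flag"].astype(bool)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def weight(self) -> pd.Series:
        return self.frame["weight_g"]

    @property
    def irrigation_flag(self) -> pd.Series:
        return self.frame["irrigation_flag"]

    def __len__(self) -> int:
        return len(self.frame)

    def gaps(self, nominal_step: pd.Timedelta = NOMINAL_STEP) -> pd.DataFrame:
        """Intervals longer than 1.5x the nominal cadence (start, end, length)."""
        idx = self.frame.index
        if len(idx) < 2:
            return pd.DataFrame(columns=["start", "end", "length"])
        d = idx.to_series().diff().iloc[1:]
        big = d[d > 1.5 * nominal_step]
        return pd.DataFrame(
            {"start": big.index - big.values, "end": big.index, "length": big.values}
        ).reset_index(drop=True)


@dataclass(eq=False)
class EnvSeries:
    """Shared environmental sensors plus per-pot VWC on one DatetimeIndex.

    Required columns: ``t_air_c``, ``rh_pct`` (in [0, 100]), ``par_umol``
    (>= 0). VWC columns (in [0, 1]) are either a single ``vwc`` column or
    per-pot ``vwc_<pot_id>`` columns.
    """

    frame: pd.DataFrame
    parse_report: ParseReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise TypeError("EnvSeries.frame must have a DatetimeIndex")
        _validate_index(f.index, "EnvSeries")
        missing = [c for c in ENV_COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"EnvSeries missing required columns: {missing}")
        rh = f["rh_pct"].to_numpy(dtype=float)
        if np.any((rh < 0) | (rh > 100)):
            raise ValueError("rh_pct must lie in [0, 100]")
        if np.any(f["par_umol"].to_numpy(dtype=float) < 0):
            raise ValueError("par_umol must be non-negative")
        for c in self.vwc_columns:
            v = f[c].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{c} must lie in [0, 1]")

    @property
    def vwc_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c == "vwc" or c.startswith("vwc_")]

    def vwc(self, pot_id: str | None = None) -> pd.Series:
        """Per-pot VWC series; falls back to the shared 'vwc' column."""
        if pot_id is not None and f"vwc_{pot_id}" in self.frame.columns:
            return self.frame[f"vwc_{pot_id}"]
        if "vwc" in self.frame.columns:
            return self.frame["vwc"]
        raise KeyError(f"no VWC column for pot {pot_id!r}")

    def __len__(self) -> int:
        return len(self.frame)


def _read_delimited(path, required: list[str], numeric: list[str], timestamp_col: str):
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    missing = [c for c in [timestamp_col, *required] if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}; found {list(raw.columns)}")
    report = ParseReport(path=str(path), n_rows=len(raw))
    ts = pd.to_datetime(raw[timestamp_col], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    report.n_dropped_timestamp = int(bad_ts.sum())

    def _exact_float(x):
        # python's float() is correctly rounded, so written values round-trip
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    vals = raw[numeric].apply(lambda col: col.map(_exact_float))
    bad_val = vals.isna().any(axis=1) & ~bad_ts
    report.n_dropped_value = int(bad_val.sum())
    keep = ~(bad_ts | bad_val)
    if not keep.any():
        raise EmptyInputError(f"{path}: zero valid rows after parsing")
    out = vals[keep]
    out.index = pd.DatetimeIndex(ts[keep])
    out = out.sort_index()
    return out, report


def read_weight_series(path, pot_id: str, timestamp_col: str = "timestamp") -> WeightSeries:
    """Parse a weight CSV (columns ``timestamp, weight_g``) into a WeightSeries.

    Rows with unparseable timestamps or non-numeric weights are dropped and
    counted in the attached :class:`ParseReport`. Raises
    :class:`~lysiphen.errors.FormatError` for missing columns and
    :class:`~lysiphen.errors.EmptyInputError` when no valid rows remain.
    """
    frame, report = _read_delimited(path, ["weight_g"], ["weight_g"], timestamp_col)
    frame["irrigation_flag"] = False
    return WeightSeries(pot_id=pot_id, frame=frame, parse_report=report)


def write_weight_series(series: WeightSeries, path) -> None:
    """Write a WeightSeries back to CSV; values round-trip bit-for-bit."""
    out = series.frame.copy()
    out.index.name = "timestamp"
    # repr() is the shortest exact decimal for a double, so values round-trip
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S", float_format=lambda x: repr(float(x)))


def read_env_series(path, timestamp_col: str = "timestamp") -> EnvSeries:
    """Parse an environment CSV (t_air_c, rh_pct, par_umol, vwc[...])."""
    try:
        header = pd.read_csv(path, nrows=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    vwc_cols = [c for c in header.columns if c == "vwc" or c.startswith("vwc_")]
    numeric = list(ENV_COLUMNS) + vwc_cols
    frame, report = _read_delimited(path, numeric, numeric, timestamp_col)
    return EnvSeries(frame=frame, parse_report=report)


def write_env_series(env: EnvSeries, path) -> None:
    out = env.frame.copy()
    out.index.name = "timestamp"
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S", float_format=lambda x: repr(float(x)))


def detect_irrigation_events(series: WeightSeries, jump_threshold: float = DEFAULT_JUMP_THRESHOLD) -> WeightSeries:
    """Flag instants whose preceding interval gained more than ``jump_threshold`` g.

    Irrigation pulses add mass abruptly; any interval with a weight increase
    above the threshold is flagged (at the interval's end instant) so that
    transpiration differencing can exclude it. Deterministic in (series,
    threshold); a monotone-decreasing series yields zero flags.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot detect irrigation events on an empty series")
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    w = series.weight.to_numpy(dtype=float)
    jumps = np.diff(w, prepend=w[0])
    flags = jumps > jump_threshold
    frame = series.frame.copy()
    frame["irrigation_flag"] = flags
    return WeightSeries(pot_id=series.pot_id, frame=frame, parse_report=series.parse_report)


def align_to_grid(
    weight: WeightSeries,
    env: EnvSeries,
    step: pd.Timedelta | str = NOMINAL_STEP,
    max_gap: pd.Timedelta | str = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Join weight and environment streams by nearest-neighbor within step/2.

    The output grid is the weight series' own timestamps restricted to the
    overlap of the two streams; each grid instant takes the nearest
    environment record within ``step/2`` (no interpolation — records without a
    close match are dropped, so data are never carried across gaps longer than
    ``max_gap``). Raises :class:`~lysiphen.errors.AlignmentError` on empty
    overlap. Output length never exceeds either input's length.
    """
    step = pd.Timedelta(step)
    max_gap = pd.Timedelta(max_gap)
    if len(weight) == 0 or len(env) == 0:
        raise AlignmentError("cannot align empty series")
    lo = max(weight.timestamps[0], env.frame.index[0])
    hi = min(weight.timestamps[-1], env.frame.index[-1])
    if lo > hi:
        raise AlignmentError(
            f"weight ({weight.timestamps[0]}..{weight.timestamps[-1]}) and env "
            f"({env.frame.index[0]}..{env.frame.index[-1]}) do not overlap"
        )
    tol = min(step / 2, max_gap)
    # boundary records still within matching tolerance of the overlap survive
    wf = weight.frame.loc[lo - tol : hi + tol]
    grid = wf.index
    env_idx = env.frame.index
    pos = env_idx.get_indexer(grid, method="nearest", tolerance=tol)
    ok = pos >= 0
    # each env record may serve at most one grid instant: on contention keep
    # the closer grid point, so the join never exceeds either input's length
    dist = np.full(len(grid), np.inf)
    dist[ok] = np.abs(grid[ok].asi8 - env_idx.asi8[pos[ok]])
    order = np.argsort(dist, kind="stable")
    seen: set[int] = set()
    keep = np.zeros(len(grid), dtype=bool)
    for i in order:
        if not ok[i] or pos[i] in seen:
            continue
        seen.add(int(pos[i]))
        keep[i] = True
    joined = wf[keep].copy()
    envpart = env.frame.iloc[pos[keep]]
    for c in envpart.columns:
        joined[c] = envpart[c].to_numpy()
    return joined
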