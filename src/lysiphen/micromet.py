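"""Micrometeorology helpers: vapor pressure deficit and clock-time windows.

The greenhouse forcing enters the water-relations traits in two ways: the
saturation deficit of the air (VPD, kPa) normalises midday transpiration, and
three fixed clock-time windows define the daily aggregates — midday
(12:00–14:00) for the transpiration/soil-moisture response, predawn
(04:00–04:30) and evening (19:00–19:30) for the daily water-balance weights.
Windows are half-open ``[start, end)`` so edge samples are never counted twice.

VPD uses the Tetens/Magnus saturation curve

    es(T) = a * exp(b * T / (T + c)),   VPD = es(T) * (1 - RH/100)

with a = 0.6108 kPa, b = 17.27, c = 237.3 °C — the standard
micrometeorological parameterisation. The constants are carried in a
:class:`MagnusConstants` record so an alternative calibration can be swapped in.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "MagnusConstants",
    "MAGNUS",
    "Window",
    "MIDDAY",
    "PREDAWN",
    "EVENING",
    "WINDOWS",
    "saturation_vapor_pressure",
    "vpd",
    "window_mean",
]


@dataclass(frozen=True)
class MagnusConstants:
    """Tetens/Magnus saturation vapor pressure constants (kPa, -, °C)."""

    a: float = 0.6108
    b: float = 17.27
    c: float = 237.3


MAGNUS = MagnusConstants()

#: Physiological temperature range accepted by :func:`saturation_vapor_pressure`.
T_AIR_RANGE = (-10.0, 60.0)


@dataclass(frozen=True)
class Window:
    """Half-open clock-time aggregation window ``[start, end)``."""

    label: str
    start: _dt.time
    end: _dt.time

    @property
    def duration(self) -> _dt.timedelta:
        ref = _dt.date(2000, 1, 1)
        return _dt.datetime.combine(ref, self.end) - _dt.datetime.combine(ref, self.start)


MIDDAY = Window("midday", _dt.time(12, 0), _dt.time(14, 0))
PREDAWN = Window("predawn", _dt.time(4, 0), _dt.time(4, 30))
EVENING = Window("evening", _dt.time(19, 0), _dt.time(19, 30))

WINDOWS = {w.label: w for w in (MIDDAY, PREDAWN, EVENING)}


def saturation_vapor_pressure(t_air, constants: MagnusConstants = MAGNUS):
    """Saturation vapor pressure es(T) in kPa (Magnus form), increasing in T.

    Parameters
    ----------
    t_air : float or array-like
        Air temperature in °C; must lie in ``T_AIR_RANGE``.
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t < T_AIR_RANGE[0]) or np.any(t > T_AIR_RANGE[1]):
        raise DomainError(
            f"air temperature outside physiological range {T_AIR_RANGE}: "
            f"min={np.min(t):.2f}, max={np.max(t):.2f}"
        )
    es = constants.a * np.exp(constants.b * t / (t + constants.c))
    return float(es) if np.isscalar(t_air) else es


def vpd(t_air, rh, constants: MagnusConstants = MAGNUS):
    """Air-saturation vapor pressure deficit in kPa.

    ``vpd = es(t_air) * (1 - rh/100)``; zero at saturation, es(T) for dry air.
    """
    r = np.asarray(rh, dtype=float)
    if np.any(r < 0.0) or np.any(r > 100.0):
        raise DomainError("relative humidity must lie in [0, 100] %")
    out = saturation_vapor_pressure(t_air, constants) * (1.0 - r / 100.0)
    return float(out) if (np.isscalar(t_air) and np.isscalar(rh)) else out


def _infer_step(index: pd.DatetimeIndex) -> pd.Timedelta | None:
    if len(index) < 2:
        return None
    diffs = index.to_series().diff().dropna()
    step = diffs.median()
    if step <= pd.Timedelta(0):
        return None
    return step


def window_mean(
    series: pd.Series,
    window: Window,
    day: _dt.date,
    step: pd.Timedelta | str | None = None,
    min_coverage: float = 0.75,
) -> float:
    """Arithmetic mean of the samples falling in ``window`` on ``day``.

    Returns ``nan`` ("missing") when in-window coverage — number of valid
    samples relative to ``window.duration / step`` — is below ``min_coverage``.
    ``step`` defaults to the median sampling interval of ``series``.
    Duplicate timestamps are deduplicated (first kept) and NaN samples dropped,
    so the result does not depend on sample order.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("window_mean expects a DatetimeIndex-indexed series")
    s = series.dropna()
    s = s[~s.index.duplicated(keep="first")].sort_index()
    start = pd.Timestamp(_dt.datetime.combine(day, window.start))
    end = pd.Timestamp(_dt.datetime.combine(day, window.end))
    sel = s[(s.index >= start) & (s.index < end)]
    if step is None:
        step = _infer_step(s.index)
    else:
        step = pd.Timedelta(step)
    if step is None:
        # cannot assess coverage on a <2-sample series
        return float(sel.mean()) if len(sel) else float("nan")
    expected = max(1.0, pd.Timedelta(window.duration) / step)
    if len(sel) / expected < min_coverage:
        return float("nan")
    return float(sel.mean())
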