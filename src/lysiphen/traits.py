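"""Whole-plant water-relations traits from the gravimetric stream.

Everything here follows from one idea: on a lysimeter, water the plant loses
shows up as system-weight decline. The derived traits are

* ``Tr`` (g min⁻¹) — whole-plant transpiration rate, minus the first
  derivative of system weight, estimated by a centered local linear
  regression so the 3-minute balance noise does not dominate;
* ``Tr_m`` — the 12:00–14:00 mean of Tr, and ``Tr_m,VPD = Tr_m / VPD_m``,
  its normalisation by midday vapor pressure deficit, which removes most
  day-to-day environmental variation from the drydown response;
* ``E`` (g d⁻¹) — daily transpiration, the predawn (04:00–04:30) minus
  evening (19:00–19:30) mean system weight of the same day;
* ``PG`` (g d⁻¹) — daily fresh plant growth, the difference of predawn
  weights on adjacent days; meaningful only when nightly irrigation returns
  the pot to capacity, i.e. in the well-irrigated and recovery phases;
* ``WUE`` (g g⁻¹) — cumulative PG over cumulative E in a fixed window
  (5 days after rewatering in the reference protocol).

Irrigation-flagged samples are excluded from the derivative: pulses add mass,
and a regression window straddling a pulse would see a spurious level shift,
so windows are additionally confined to contiguous segments between pulses.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from . import micromet
from .design import PhaseDesign
from .errors import PhaseError
from .micromet import EVENING, MIDDAY, PREDAWN, window_mean
from .timeseries import EnvSeries, WeightSeries, align_to_grid

__all__ = [
    "transpiration_rate",
    "daily_transpiration",
    "daily_plant_growth",
    "wue",
    "midday_tr_vpd",
    "build_daily_traits",
]

#: Below this midday VPD (kPa) the normalisation Tr_m/VPD_m is unreliable.
VPD_EPSILON = 0.05

#: Default half-width (samples) of the local-linear derivative window (~30 min).
DEFAULT_HALFWIDTH = 5


def transpiration_rate(series: WeightSeries, smoothing_halfwidth: int = DEFAULT_HALFWIDTH) -> pd.Series:
    """Transpiration rate Tr(t) = -dW/dt in g min⁻¹ from the weight stream.

    The derivative at each instant is the slope of a least-squares line over a
    centered window of ``2*smoothing_halfwidth + 1`` samples, restricted to
    the contiguous run between irrigation pulses that contains the instant
    (flagged samples themselves are excluded). ``smoothing_halfwidth=0``
    degrades to signed forward differences, whose daily integral telescopes
    exactly to the day's weight loss.

    Negative estimates (balance noise, condensation) are clipped to zero; the
    clip count is reported in ``result.attrs["n_clipped"]``. Instants whose
    window holds fewer than two usable samples are missing (NaN).

    Adding a constant to every weight leaves Tr unchanged.
    """
    if smoothing_halfwidth < 0:
        raise ValueError("smoothing_halfwidth must be >= 0")
    idx = series.timestamps
    n = len(series)
    w = series.weight.to_numpy(dtype=float)
    flagged = series.irrigation_flag.to_numpy(dtype=bool)
    t_min = (idx.asi8 - idx.asi8[0]) / 60e9  # minutes
    segment = np.cumsum(flagged)  # windows may not cross a pulse
    tr = np.full(n, np.nan)

    if smoothing_halfwidth == 0:
        for i in range(n - 1):
            if flagged[i] or flagged[i + 1] or segment[i] != segment[i + 1]:
                continue
            dt = t_min[i + 1] - t_min[i]
            if dt > 0:
                tr[i] = -(w[i + 1] - w[i]) / dt
    else:
        h = smoothing_halfwidth
        for i in range(n):
            if flagged[i]:
                continue
            lo, hi = max(0, i - h), min(n, i + h + 1)
            sl = slice(lo, hi)
            use = (~flagged[sl]) & (segment[sl] == segment[i])
            if use.sum() < 2:
                continue
            tt = t_min[sl][use]
            ww = w[sl][use]
            tt = tt - tt.mean()
            denom = float(tt @ tt)
            if denom <= 0:
                continue
            tr[i] = -float(tt @ (ww - ww.mean())) / denom

    n_clipped = int(np.sum(tr < 0))
    tr = np.where(tr < 0, 0.0, tr)
    out = pd.Series(tr, index=idx, name="tr_g_min")
    out.attrs["n_clipped"] = n_clipped
    return out


def daily_transpiration(series: WeightSeries, day: _dt.date, clip_negative: bool = True) -> float:
    """Daily transpiration E = mean predawn weight - mean evening weight (g d⁻¹).

    Both window means are taken on ``day``; missing (NaN) if either window
    lacks coverage. Small negative values (noise on a zero-loss day) are
    clipped to zero unless ``clip_negative`` is False.
    """
    predawn = window_mean(series.weight, PREDAWN, day)
    evening = window_mean(series.weight, EVENING, day)
    e = predawn - evening
    if clip_negative and e < 0:
        e = 0.0
    return float(e)


def daily_plant_growth(series: WeightSeries, day: _dt.date, phase: str = "well_irrigated") -> float:
    """Daily fresh plant growth PG = predawn(day+1) - predawn(day) in g d⁻¹.

    Defined only when nightly irrigation re-saturates the pot, so the predawn
    weight difference reflects plant mass, not soil water. Raises
    :class:`~lysiphen.errors.PhaseError` outside the well-irrigated /
    water-recovery phases.
    """
    if phase not in ("well_irrigated", "water_recovery"):
        raise PhaseError(
            f"plant growth from predawn weights is undefined in phase {phase!r}: "
            "the pot must return to capacity overnight"
        )
    p0 = window_mean(series.weight, PREDAWN, day)
    p1 = window_mean(series.weight, PREDAWN, day + _dt.timedelta(days=1))
    return float(p1 - p0)


def wue(pg_series, e_series, window_days: int = 5) -> float:
    """Water use efficiency ΣPG/ΣE (g g⁻¹) over the first ``window_days`` days.

    Missing (NaN) if either series lacks coverage of the window or ΣE is zero.
    """
    pg = np.asarray(pd.Series(pg_series), dtype=float)[:window_days]
    e = np.asarray(pd.Series(e_series), dtype=float)[:window_days]
    if len(pg) < window_days or len(e) < window_days:
        return float("nan")
    if np.any(np.isnan(pg)) or np.any(np.isnan(e)):
        return float("nan")
    total_e = float(e.sum())
    if total_e == 0:
        return float("nan")
    return float(pg.sum()) / total_e


def midday_tr_vpd(tr_m: float, vpd_m: float, eps: float = VPD_EPSILON) -> float:
    """VPD-normalised midday transpiration Tr_m/VPD_m (g min⁻¹ kPa⁻¹).

    Missing when VPD_m <= ``eps`` (default 0.05 kPa) to avoid blow-up on
    near-saturated days. Scale-invariant: doubling both inputs is a no-op.
    """
    if not np.isfinite(tr_m) or not np.isfinite(vpd_m) or vpd_m <= eps:
        return float("nan")
    return float(tr_m) / float(vpd_m)


def build_daily_traits(
    weight: WeightSeries,
    env: EnvSeries,
    phases: PhaseDesign | None = None,
    smoothing_halfwidth: int = DEFAULT_HALFWIDTH,
    vpd_eps: float = VPD_EPSILON,
) -> pd.DataFrame:
    """Per plant-day trait table for one pot.

    Joins the streams, derives Tr, VPD and the daily aggregates, and returns
    one row per calendar day with columns ``pot_id, date, phase, tr_m, vpd_m,
    tr_m_vpd, e_daily, pg, vwc_m``. PG is filled only for days whose phase
    permits it (well-irrigated / water-recovery with next-day coverage).
    """
    joined = align_to_grid(weight, env)
    tr = transpiration_rate(weight, smoothing_halfwidth)
    vpd_series = pd.Series(
        micromet.vpd(joined["t_air_c"].to_numpy(), joined["rh_pct"].to_numpy()),
        index=joined.index,
    )
    vwc_series = None
    for cand in (f"vwc_{weight.pot_id}", "vwc"):
        if cand in joined.columns:
            vwc_series = joined[cand]
            break

    rows = []
    for day in sorted({ts.date() for ts in joined.index}):
        phase = phases.phase_of(day) if phases is not None else None
        tr_m = window_mean(tr, MIDDAY, day)
        vpd_m = window_mean(vpd_series, MIDDAY, day)
        vwc_m = window_mean(vwc_series, MIDDAY, day) if vwc_series is not None else float("nan")
        e_daily = daily_transpiration(weight, day)
        pg = float("nan")
        if phase in ("well_irrigated", "water_recovery"):
            pg = daily_plant_growth(weight, day, phase=phase)
        rows.append(
            {
                "pot_id": weight.pot_id,
                "date": day,
                "phase": phase,
                "tr_m": tr_m,
                "vpd_m": vpd_m,
                "tr_m_vpd": midday_tr_vpd(tr_m, vpd_m, eps=vpd_eps),
                "e_daily": e_daily,
                "pg": pg,
                "vwc_m": vwc_m,
            }
        )
    return pd.DataFrame(rows)
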