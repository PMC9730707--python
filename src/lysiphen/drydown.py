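"""Two-segment (broken-stick) fit of the transpiration–soil-moisture response.

During a progressive drydown, VPD-normalised midday transpiration y =
Tr_m,VPD stays on a plateau while soil water is plentiful and declines
linearly once the volumetric water content x = VWC falls below a critical
value θ_cri:

    y = a                     for x >= θ_cri
    y = a - k (θ_cri - x)     for x <  θ_cri

with plateau ``a`` (g min⁻¹ kPa⁻¹), decline slope ``k`` >= 0
((g min⁻¹ kPa⁻¹) per (m³ m⁻³)) and breakpoint ``θ_cri`` (m³ m⁻³). θ_cri is
the quantity of agronomic interest: it marks where stomatal closure begins
and is the candidate trigger for deficit irrigation.

Conditional on θ the model is linear in (a, k) through the hinge basis
x' = min(x - θ, 0), so the fit profiles the residual sum of squares over a
θ grid and refines the winning cell by golden-section search — globally
robust, no nonconvex joint optimisation. Ties in RSS break toward the
smaller (more conservative) θ.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, DegeneratePartitionError, FitError

__all__ = [
    "DrydownPoint",
    "DrydownFit",
    "hinge_predict",
    "conditional_ls",
    "fit_piecewise",
    "bootstrap_uncertainty",
    "aggregate_replicates",
    "dynamic_period_points",
    "plot_fit",
]

#: Number of breakpoint candidates profiled before golden-section refinement.
DEFAULT_GRID_RESOLUTION = 200

#: Minimum day-over-day midday VWC drop (m³ m⁻³) for a plant-day to count as
#: part of the dynamic drydown (excludes the asymptotic tail where the pot has
#: effectively stopped losing water).
DEFAULT_MIN_DAILY_DROP = 0.0015

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class DrydownPoint:
    """One plant-day of the response: midday means of VWC and Tr_m,VPD."""

    vwc: float
    tr_m_vpd: float
    pot_id: str = ""
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwc <= 1.0:
            raise ValueError("vwc must lie in [0, 1]")
        if self.tr_m_vpd < 0:
            raise ValueError("tr_m_vpd must be non-negative")


@dataclass
class DrydownFit:
    """Fitted two-segment response for one pot (or one pooled dataset).

    ``k`` follows the decline-positive convention: it equals the piecewise
    model's slope of y against VWC below the breakpoint, positive when
    transpiration falls as soil dries.
    """

    a: float
    k: float
    theta_cri: float
    r2: float
    n_points: int
    rss: float
    se_a: float = float("nan")
    se_k: float = float("nan")
    se_theta: float = float("nan")
    converged: bool = True
    label: str = ""

    def predict(self, vwc) -> np.ndarray:
        return hinge_predict(vwc, self.a, self.k, self.theta_cri)


def hinge_predict(vwc, a: float, k: float, theta: float) -> np.ndarray:
    """Evaluate the two-segment model at ``vwc``."""
    x = np.minimum(np.asarray(vwc, dtype=float) - theta, 0.0)
    return a + k * x


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        v = points["vwc"].to_numpy(dtype=float)
        y = points["tr_m_vpd"].to_numpy(dtype=float)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], DrydownPoint):
            v = np.array([p.vwc for p in pts], dtype=float)
            y = np.array([p.tr_m_vpd for p in pts], dtype=float)
        else:
            arr = np.asarray(pts, dtype=float)
            v, y = arr[:, 0], arr[:, 1]
    ok = np.isfinite(v) & np.isfinite(y)
    return v[ok], y[ok]


def conditional_ls(points, theta: float) -> tuple[float, float, float]:
    """Least squares of the two-segment model with the breakpoint held at ``theta``.

    Returns ``(a, k, rss)`` from the simple regression of y on the hinge
    predictor x' = min(VWC - theta, 0). Requires at least two points strictly
    below and two at/above theta, else
    :class:`~lysiphen.errors.DegeneratePartitionError`.
    """
    v, y = _as_arrays(points)
    n_below = int(np.sum(v < theta))
    n_above = int(np.sum(v >= theta))
    if n_below < 2 or n_above < 2:
        raise DegeneratePartitionError(
            f"theta={theta:.4g}: {n_below} point(s) below, {n_above} at/above; need >= 2 each"
        )
    x = np.minimum(v - theta, 0.0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegeneratePartitionError(f"theta={theta:.4g}: hinge predictor is constant")
    k = float(xc @ (y - y.mean())) / sxx
    a = float(y.mean() - k * x.mean())
    resid = y - (a + k * x)
    return a, k, float(resid @ resid)


def _profile_rss(v: np.ndarray, y: np.ndarray, theta: float) -> float:
    try:
        return conditional_ls(np.column_stack([v, y]), theta)[2]
    except DegeneratePartitionError:
        return np.inf


def _golden_section(f, lo: float, hi: float, tol: float = 1e-7, max_iter: int = 200) -> float:
    """Deterministic bounded golden-section minimiser; ties drift to the low end."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return c if fc <= fd else d


def fit_piecewise(
    points,
    grid_resolution: int = DEFAULT_GRID_RESOLUTION,
    refine: bool = True,
    label: str = "",
) -> DrydownFit:
    """Profile-RSS fit of the two-segment response; returns a :class:`DrydownFit`.

    Breakpoint candidates span the 2nd-smallest to 2nd-largest observed VWC
    (so both segments can keep two points): a ``grid_resolution``-point
    uniform grid plus candidates inside every inter-point interval, with the
    winning cell refined by golden-section search — equivalent to exhaustive
    enumeration of the RSS profile. Candidates that split the data
    degenerately are skipped; RSS ties break toward the smaller θ.
    ``r2 = 1 - RSS/TSS``. ``se_a``/``se_k`` are the conditional (θ fixed at
    its estimate) OLS standard errors; ``se_theta`` is left to
    :func:`bootstrap_uncertainty`.
    """
    v, y = _as_arrays(points)
    n = len(v)
    if n < 6:
        raise FitError(f"need >= 6 points to fit a breakpoint, got {n}")
    vs = np.sort(v)
    lo, hi = vs[1], vs[-2]
    if not lo < hi:
        raise FitError("VWC values do not span an interior breakpoint range")
    # The RSS profile is smooth only between consecutive observed VWC values
    # (the hinge assignment changes at each data point), so a uniform grid is
    # supplemented with candidates inside every inter-point interval; the
    # winning cell is then refined by golden-section search. This keeps the
    # search equivalent to exhaustive enumeration even when narrow RSS dips
    # fall between irregularly spaced points.
    grid = np.linspace(lo, hi, max(int(grid_resolution), 3))
    interior = np.unique(vs[(vs >= lo) & (vs <= hi)])
    per_interval = [
        np.linspace(a_, b_, 9)[1:-1]
        for a_, b_ in zip(interior[:-1], interior[1:])
        if b_ > a_
    ]
    cands = np.unique(np.concatenate([grid, interior, *per_interval]))
    rss_cands = np.array([_profile_rss(v, y, th) for th in cands])
    if not np.any(np.isfinite(rss_cands)):
        raise FitError(
            "no candidate breakpoint admits >= 2 points on each side; "
            f"VWC range [{vs[0]:.4g}, {vs[-1]:.4g}] with n={n}"
        )
    best = int(np.argmin(rss_cands))  # np.argmin takes the first (smallest θ) on ties
    theta = float(cands[best])
    best_rss = float(rss_cands[best])
    if refine:
        left = cands[max(best - 1, 0)]
        right = cands[min(best + 1, len(cands) - 1)]
        if right > left:
            cand = float(_golden_section(lambda th: _profile_rss(v, y, th), left, right))
            cand_rss = _profile_rss(v, y, cand)
            if np.isfinite(cand_rss) and (
                cand_rss < best_rss or (cand_rss == best_rss and cand < theta)
            ):
                theta, best_rss = cand, float(cand_rss)
    a, k, rss = conditional_ls(np.column_stack([v, y]), theta)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if rss <= 1e-12 else 0.0
    # conditional OLS standard errors (treat theta as known)
    dof = n - 2
    sigma2 = rss / dof if dof > 0 else float("nan")
    x = np.minimum(v - theta, 0.0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    se_k = float(np.sqrt(sigma2 / sxx)) if sxx > 0 else float("nan")
    se_a = float(np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))) if sxx > 0 else float("nan")
    return DrydownFit(
        a=a,
        k=k,
        theta_cri=theta,
        r2=float(np.clip(r2, 0.0, 1.0)),
        n_points=n,
        rss=rss,
        se_a=se_a,
        se_k=se_k,
        converged=True,
        label=label,
    )


def bootstrap_uncertainty(
    points,
    n_boot: int = 200,
    seed: int = 0,
    grid_resolution: int = DEFAULT_GRID_RESOLUTION,
) -> tuple[float, float, float]:
    """Case-resampling bootstrap standard errors ``(se_a, se_k, se_theta)``.

    Resamples plant-days with replacement and refits; refits that fail
    (degenerate resample) are dropped and counted. If more than half fail the
    fit is flagged unstable (warning) and the SEs are returned as NaN.
    Bit-reproducible for fixed (points, n_boot, seed).
    """
    v, y = _as_arrays(points)
    rng = np.random.default_rng(seed)
    n = len(v)
    fits: list[tuple[float, float, float]] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            f = fit_piecewise(np.column_stack([v[idx], y[idx]]), grid_resolution=grid_resolution)
            fits.append((f.a, f.k, f.theta_cri))
        except FitError:
            n_failed += 1
    if n_failed > n_boot / 2:
        warnings.warn(
            f"unstable fit: {n_failed}/{n_boot} bootstrap refits failed; SEs set missing",
            stacklevel=2,
        )
        return (float("nan"), float("nan"), float("nan"))
    arr = np.asarray(fits)
    sd = arr.std(axis=0, ddof=1)
    return (float(sd[0]), float(sd[1]), float(sd[2]))


def aggregate_replicates(fits, group: str = "") -> pd.DataFrame:
    """Between-pot mean, SD and n of (a, k, θ_cri, R²) across replicate fits.

    Only converged fits count; fewer than two raises
    :class:`~lysiphen.errors.AggregationError`. This between-plant spread is
    the replicate ± reported alongside variety estimates (the bootstrap SE is
    the within-plant alternative).
    """
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise AggregationError(
            f"group {group!r}: need >= 2 converged replicate fits, got {len(good)}"
        )
    rows = []
    for param in ("a", "k", "theta_cri", "r2"):
        vals = np.array([getattr(f, param) for f in good], dtype=float)
        rows.append(
            {
                "group": group,
                "parameter": param,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "n": len(good),
            }
        )
    return pd.DataFrame(rows)


def dynamic_period_points(
    traits: pd.DataFrame,
    phase: str = "progressive_drought",
    min_daily_drop: float = DEFAULT_MIN_DAILY_DROP,
) -> pd.DataFrame:
    """Select the drought-phase plant-days that form the drydown response.

    Takes a per-day traits table (``build_daily_traits`` output) and keeps
    days in ``phase`` with valid midday values while the pot is still drying
    dynamically — i.e. the midday VWC dropped by at least ``min_daily_drop``
    since the previous day. Once transpiration has collapsed the VWC flattens
    at its terminal value; those quasi-static days carry no information about
    the response curve and are excluded.

    Returns a DataFrame with columns ``vwc``, ``tr_m_vpd``, ``pot_id``, ``date``.
    """
    df = traits.sort_values("date")
    if "phase" in df.columns and df["phase"].notna().any():
        df = df[df["phase"] == phase]
    df = df[np.isfinite(df["vwc_m"]) & np.isfinite(df["tr_m_vpd"])]
    if len(df) == 0:
        return pd.DataFrame(columns=["vwc", "tr_m_vpd", "pot_id", "date"])
    drop = -df["vwc_m"].diff()
    keep = drop.isna() | (drop >= min_daily_drop)
    df = df[keep]
    return pd.DataFrame(
        {
            "vwc": df["vwc_m"].to_numpy(),
            "tr_m_vpd": df["tr_m_vpd"].to_numpy(),
            "pot_id": df["pot_id"].to_numpy(),
            "date": df["date"].to_numpy(),
        }
    )


def plot_fit(points, fit: DrydownFit, ax=None):
    """Scatter the (VWC, Tr_m,VPD) points with the fitted hinge overlaid."""
    import matplotlib.pyplot as plt

    v, y = _as_arrays(points)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(v, y, "o", ms=4, alpha=0.7, label="plant-days")
    xs = np.linspace(v.min(), v.max(), 200)
    ax.plot(xs, fit.predict(xs), "-", lw=2, label="two-segment fit")
    ax.axvline(fit.theta_cri, ls="--", lw=1, color="gray")
    ax.annotate(
        rf"$\theta_{{cri}}$={fit.theta_cri:.4f}",
        (fit.theta_cri, ax.get_ylim()[0]),
        textcoords="offset points",
        xytext=(4, 6),
        fontsize=8,
    )
    ax.set_xlabel("midday VWC (m$^3$ m$^{-3}$)")
    ax.set_ylabel("Tr$_{m,VPD}$ (g min$^{-1}$ kPa$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    return ax
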