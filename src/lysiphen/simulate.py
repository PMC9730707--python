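"""Soil–plant–atmosphere pot simulator and FPKM matrix generator.

Every input the analysis pipeline consumes can be generated here with known
ground truth: a gravimetric drydown experiment (3-minute system-weight and
sensor streams for a pot on a weighing platform) and a 2-condition,
3-replicate FPKM expression matrix with labelled differential genes.

Pot water balance (Euler stepping at the 3-minute cadence)::

    Tr(t)   = g_ref * PAR/(PAR + p50) * VPD(t) * f(VWC)
    f(VWC)  = 1                                  for VWC >= theta_true
            = max(0, 1 - (k/a_eff)(theta - VWC)) below
    W(t+Δ)  = W(t) - Tr Δ + irrigation - drainage + growth

where ``a_eff`` is the midday plateau implied by ``g_ref`` under the
deterministic forcing, chosen so that the *emitted* midday
(VWC, Tr_m/VPD_m) relation is exactly the two-segment response with
parameters (a_eff, k_true, theta_true). Drainage is an instantaneous clip at
pot capacity during irrigation pulses, so predawn weights sit at capacity
under the well-watered schedule and predawn growth bookkeeping is exact.
Fresh-mass growth is credited during the nightly irrigation window
(0:00–4:00) so the predawn/evening transpiration windows see constant plant
mass; growth pauses while the pot is below ``theta_true`` (stress–growth
coupling, configurable).

The substrate covers a 1.5 L pot; the pot surface is assumed covered (as on
commercial gravimetric platforms), so no soil evaporation term appears and
night transpiration is zero (PAR = 0).

Two climate presets matter. ``EnvParams()`` is a generic bright-greenhouse
day (T 12–32 °C, RH 35–90 %, PAR peaking ~1200 µmol m⁻² s⁻¹).
``PROTECTED_CULTIVATION`` is the humid plastic-tunnel profile used as the
drydown default: with a 1.5 L root volume, a multi-week progressive drydown
(the regime the response fit needs, ~one midday point per day for 20+ days)
requires a daily water demand of only ~15–20 g — i.e. low evaporative
demand, which is exactly what protected strawberry cultivation looks like.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SimulationError
from .micromet import MIDDAY, vpd as _vpd
from .timeseries import EnvSeries, WeightSeries

__all__ = [
    "PlantParams",
    "PotParams",
    "EnvParams",
    "PROTECTED_CULTIVATION",
    "IrrigationSchedule",
    "SimTruth",
    "SimResult",
    "simulate_env",
    "simulate_drydown",
    "variety_preset",
    "simulate_fpkm",
]

STEP_MINUTES = 3
STEPS_PER_DAY = 24 * 60 // STEP_MINUTES
EPOCH = _dt.datetime(2022, 4, 1)


@dataclass(frozen=True)
class PlantParams:
    """Generative plant parameters.

    g_ref : transpiration coefficient, g min⁻¹ kPa⁻¹ at saturating PAR.
    theta_true : critical VWC (m³ m⁻³) below which stomata begin closing.
    k_true : decline slope of the midday response, (g min⁻¹ kPa⁻¹)/(m³ m⁻³).
    growth_rate : fresh-mass gain, g d⁻¹ (under non-stressed conditions);
        default scaled to the daily demand so 5-day WUE sits near 0.045 g g⁻¹.
    par_half_sat : PAR half-saturation of the light response, µmol m⁻² s⁻¹.
    """

    g_ref: float = 0.10
    theta_true: float = 0.15
    k_true: float = 3.0
    growth_rate: float = 0.79
    par_half_sat: float = 200.0

    def __post_init__(self) -> None:
        for name in ("g_ref", "theta_true", "k_true", "growth_rate", "par_half_sat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.05 < self.theta_true < 0.35:
            raise ValueError("theta_true must lie in (0.05, 0.35)")


@dataclass(frozen=True)
class PotParams:
    """Pot and balance parameters (1.5 L container, porous ceramic substrate)."""

    substrate_volume_l: float = 1.5
    vwc_saturation: float = 0.30  # container capacity after free drainage
    vwc_residual: float = 0.02
    tare_g: float = 650.0
    noise_sd: float = 0.1  # balance observation noise, g

    def __post_init__(self) -> None:
        if not 0 <= self.vwc_residual < self.vwc_saturation <= 1:
            raise ValueError("need 0 <= vwc_residual < vwc_saturation <= 1")
        if self.substrate_volume_l <= 0:
            raise ValueError("substrate_volume_l must be positive")

    @property
    def water_capacity_g(self) -> float:
        return self.vwc_saturation * self.substrate_volume_l * 1000.0


@dataclass(frozen=True)
class EnvParams:
    """Diurnal forcing: sinusoids symmetric about solar noon, plus optional noise."""

    t_min: float = 12.0
    t_max: float = 32.0
    rh_min: float = 35.0
    rh_max: float = 90.0
    par_peak: float = 1200.0
    daylight: tuple[float, float] = (7.0, 19.0)
    solar_noon: float = 13.0
    t_noise_sd: float = 0.3
    rh_noise_sd: float = 1.5
    par_noise_frac: float = 0.02


#: Humid plastic-tunnel climate: the drydown default (see module docstring).
PROTECTED_CULTIVATION = EnvParams(
    t_min=12.0, t_max=20.0, rh_min=82.0, rh_max=97.0, par_peak=1000.0,
    t_noise_sd=0.0, rh_noise_sd=0.0, par_noise_frac=0.0,
)


@dataclass(frozen=True)
class IrrigationSchedule:
    """Nightly fertigation pulses plus the rewatering policy.

    Pulses run ``pulse_seconds`` at each hour in ``pulse_hours`` (oversaturated
    — excess drains instantly at capacity). Irrigation is on for the first
    ``well_days`` nights; afterwards the policy decides:

    - ``"none"``: progressive drought to the end of the run;
    - ``"ck"``: irrigation every night (well-watered control);
    - ``"rewater_at_theta"``: resume the night after VWC reaches the plant's
      theta_true (deficit irrigation triggered at the critical threshold);
    - ``"rewater_at_wilting"``: resume once the stomatal factor f falls to
      ``wilting_fraction`` (severe drought).
    """

    pulse_hours: tuple[int, ...] = (0, 1, 2, 3)
    pulse_seconds: float = 240.0
    pulse_rate_g_s: float = 1.0
    well_days: int = 1
    policy: str = "none"
    wilting_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.policy not in ("none", "ck", "rewater_at_theta", "rewater_at_wilting"):
            raise ValueError(f"unknown irrigation policy {self.policy!r}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic streams."""

    plant: PlantParams
    pot: PotParams
    schedule: IrrigationSchedule
    a_eff: float
    drought_start: _dt.date | None
    recovery_start: _dt.date | None
    daily: pd.DataFrame  # date, tr_integral_g, tr_window_g, growth_g, irrigation_g, drainage_g, vwc_midday, tr_vpd_midday
    ledger: dict

    def phase_of(self, day: _dt.date) -> str:
        if self.drought_start is None or day < self.drought_start:
            return "well_irrigated"
        if self.recovery_start is not None and day >= self.recovery_start:
            return "water_recovery"
        return "progressive_drought"


@dataclass
class SimResult:
    weight: WeightSeries
    env: EnvSeries
    truth: SimTruth


def _diurnal(env: EnvParams, hours: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic diurnal components at clock ``hours`` (fractional)."""
    phase = np.cos(2 * np.pi * (hours - env.solar_noon) / 24.0)
    t_air = env.t_min + (env.t_max - env.t_min) * 0.5 * (1.0 + phase)
    rh = env.rh_max - (env.rh_max - env.rh_min) * 0.5 * (1.0 + phase)
    d0, d1 = env.daylight
    frac = (hours - d0) / (d1 - d0)
    par = np.where((frac > 0) & (frac < 1), env.par_peak * np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    return t_air, rh, par


def simulate_env(days: int, seed: int = 0, params: EnvParams = EnvParams(), noise: bool = True) -> EnvSeries:
    """Seeded 3-minute diurnal forcing (T, RH, PAR) for ``days`` days.

    Sinusoidal shapes symmetric about solar noon with optional Gaussian
    jitter; RH stays within its configured bounds and PAR is identically
    zero outside the daylight window (so 00:00–04:00 is always dark).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    n = days * STEPS_PER_DAY
    idx = pd.date_range(EPOCH, periods=n, freq=f"{STEP_MINUTES}min")
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    t_air, rh, par = _diurnal(params, hours)
    if noise:
        rng = np.random.default_rng(seed)
        t_air = t_air + rng.normal(0, params.t_noise_sd, n)
        rh = np.clip(rh + rng.normal(0, params.rh_noise_sd, n), params.rh_min, params.rh_max)
        day_mask = par > 0
        par = np.where(day_mask, np.clip(par * (1 + rng.normal(0, params.par_noise_frac, n)), 0, None), 0.0)
    frame = pd.DataFrame({"t_air_c": t_air, "rh_pct": rh, "par_umol": par}, index=idx)
    return EnvSeries(frame=frame)


def _midday_plateau(plant: PlantParams, env: EnvParams) -> float:
    """Effective midday plateau a_eff = Σ g·s·VPD / Σ VPD over the midday window.

    This is the value the pipeline's ratio of window means converges to when
    soil water is plentiful, so the emitted midday response is exactly the
    two-segment model with plateau a_eff.
    """
    n = STEPS_PER_DAY
    hours = np.arange(n) * STEP_MINUTES / 60.0
    t_air, rh, par = _diurnal(env, hours)
    v = _vpd(t_air, rh)
    s = par / (par + plant.par_half_sat)
    h0 = MIDDAY.start.hour + MIDDAY.start.minute / 60.0
    h1 = MIDDAY.end.hour + MIDDAY.end.minute / 60.0
    m = (hours >= h0) & (hours < h1)
    denom = float(np.sum(v[m]))
    if denom <= 0:
        raise SimulationError("midday VPD sums to zero under this climate")
    return plant.g_ref * float(np.sum(s[m] * v[m])) / denom


def simulate_drydown(
    plant: PlantParams,
    pot: PotParams = PotParams(),
    schedule: IrrigationSchedule = IrrigationSchedule(),
    days: int = 26,
    seed: int = 0,
    env_params: EnvParams = PROTECTED_CULTIVATION,
    env_noise: bool = False,
    initial_vwc: float | None = None,
    initial_plant_mass_g: float = 20.0,
    pot_id: str = "pot1",
) -> SimResult:
    """Simulate a pot on the weighing platform for ``days`` days.

    Emits the observed weight stream (with balance noise ``pot.noise_sd``; the
    underlying balance is exact), the environment stream with the pot's true
    VWC, and a :class:`SimTruth` record holding the generative parameters,
    per-day transpiration integrals, the noiseless midday response pairs and
    a conservation ledger (irrigation − drainage − ΣTrΔt + growth = ΔW to
    float precision).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    env = simulate_env(days, seed=seed + 1, params=env_params, noise=env_noise)
    idx = env.frame.index
    n = len(idx)
    t_air = env.frame["t_air_c"].to_numpy()
    rh = env.frame["rh_pct"].to_numpy()
    par = env.frame["par_umol"].to_numpy()
    vpd_arr = _vpd(t_air, rh)
    s_arr = par / (par + plant.par_half_sat)
    a_eff = _midday_plateau(plant, env_params)
    theta = plant.theta_true
    slope_frac = plant.k_true / a_eff  # fractional stomatal decline per m³ m⁻³
    vol_g = pot.substrate_volume_l * 1000.0
    cap = pot.water_capacity_g

    if initial_vwc is None:
        initial_vwc = pot.vwc_saturation
    if not pot.vwc_residual <= initial_vwc <= pot.vwc_saturation:
        raise SimulationError("initial_vwc outside [residual, saturation]")
    water = initial_vwc * vol_g
    mass = float(initial_plant_mass_g)

    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    dates = np.array([ts.date() for ts in idx])
    # per-step irrigation seconds under the nightly pulse pattern
    pulse_sec = np.zeros(n)
    for ph in schedule.pulse_hours:
        start, end = ph * 60.0, ph * 60.0 + schedule.pulse_seconds / 60.0
        minutes = hours * 60.0
        overlap = np.clip(np.minimum(minutes + STEP_MINUTES, end) - np.maximum(minutes, start), 0, None)
        pulse_sec += overlap * 60.0
    growth_window = (hours >= 0.0) & (hours < 4.0)
    growth_per_step = plant.growth_rate / growth_window[:STEPS_PER_DAY].sum()

    irrigation_on = True  # first night(s)
    rewatered = schedule.policy == "ck"
    drought_start: _dt.date | None = None
    recovery_start: _dt.date | None = None

    w_obs = np.empty(n)
    tr_step = np.empty(n)
    growth_step = np.zeros(n)
    irr_step = np.zeros(n)
    drain_step = np.zeros(n)
    vwc_arr = np.empty(n)

    total = {"tr": 0.0, "irrigation": 0.0, "drainage": 0.0, "growth": 0.0}
    w_start = pot.tare_g + water + mass

    day_counter = -1
    for i in range(n):
        if hours[i] == 0.0:  # midnight: update schedule state
            day_counter += 1
            vwc_now = water / vol_g
            f_now = 1.0 if vwc_now >= theta else max(0.0, 1.0 - slope_frac * (theta - vwc_now))
            if day_counter < schedule.well_days or rewatered:
                irrigation_on = True
            elif schedule.policy == "rewater_at_theta" and vwc_now <= theta:
                rewatered, irrigation_on = True, True
            elif schedule.policy == "rewater_at_wilting" and f_now <= schedule.wilting_fraction:
                rewatered, irrigation_on = True, True
            else:
                irrigation_on = False
            today = dates[i]
            if not irrigation_on and drought_start is None:
                drought_start = today
            if irrigation_on and drought_start is not None and recovery_start is None:
                recovery_start = today

        if irrigation_on and pulse_sec[i] > 0:
            add = schedule.pulse_rate_g_s * pulse_sec[i]
            spill = max(0.0, water + add - cap)
            water += add - spill
            irr_step[i] = add
            drain_step[i] = spill  # instantaneous drainage at capacity
            total["irrigation"] += add
            total["drainage"] += spill

        if growth_window[i]:
            vwc_now = water / vol_g
            if irrigation_on or vwc_now >= theta:
                mass += growth_per_step
                growth_step[i] = growth_per_step
                total["growth"] += growth_per_step

        vwc_now = water / vol_g
        vwc_arr[i] = vwc_now
        if vwc_now < 0:
            raise SimulationError("negative VWC: parameters drain the pot below zero")
        f = 1.0 if vwc_now >= theta else max(0.0, 1.0 - slope_frac * (theta - vwc_now))
        tr = plant.g_ref * s_arr[i] * vpd_arr[i] * f  # g min⁻¹
        loss = min(tr * STEP_MINUTES, water)
        tr_step[i] = loss
        water -= loss
        total["tr"] += loss
        w_obs[i] = pot.tare_g + water + mass

    if pot.noise_sd > 0:
        w_obs = np.clip(w_obs + rng.normal(0, pot.noise_sd, n), 0, None)

    weight_frame = pd.DataFrame({"weight_g": w_obs, "irrigation_flag": False}, index=idx)
    weight = WeightSeries(pot_id=pot_id, frame=weight_frame)
    env.frame[f"vwc_{pot_id}"] = vwc_arr

    # daily truth: integrals, growth, and the noiseless midday response pair
    daily_rows = []
    mid0 = MIDDAY.start.hour + MIDDAY.start.minute / 60.0
    mid1 = MIDDAY.end.hour + MIDDAY.end.minute / 60.0
    win0, win1 = 4.25, 19.25  # predawn/evening window midpoints
    for day in pd.unique(dates):
        m = dates == day
        mid = m & (hours >= mid0) & (hours < mid1)
        win = m & (hours >= win0) & (hours < win1)
        vpd_mid = vpd_arr[mid]
        tr_mid_rate = tr_step[mid] / STEP_MINUTES
        tr_vpd_mid = float(tr_mid_rate.mean() / vpd_mid.mean()) if vpd_mid.mean() > 0 else np.nan
        daily_rows.append(
            {
                "date": day,
                "tr_integral_g": float(tr_step[m].sum()),
                "tr_window_g": float(tr_step[win].sum()),
                "growth_g": float(growth_step[m].sum()),
                "irrigation_g": float(irr_step[m].sum()),
                "drainage_g": float(drain_step[m].sum()),
                "vwc_midday": float(vwc_arr[mid].mean()),
                "tr_vpd_midday": tr_vpd_mid,
            }
        )
    ledger = dict(total)
    ledger["w_start"] = w_start
    ledger["w_end"] = pot.tare_g + water + mass
    truth = SimTruth(
        plant=plant,
        pot=pot,
        schedule=schedule,
        a_eff=a_eff,
        drought_start=drought_start,
        recovery_start=recovery_start,
        daily=pd.DataFrame(daily_rows),
        ledger=ledger,
    )
    return SimResult(weight=weight, env=env, truth=truth)


#: Per-variety (theta_cri, k) generative truth; decline-positive k convention.
VARIETY_PRESETS = {
    "hongyan": {"theta_true": 0.1944, "k_true": 2.3915},
    "xiangye": {"theta_true": 0.1410, "k_true": 4.6011},
    "zhangji": {"theta_true": 0.1327, "k_true": 2.7851},
}


def variety_preset(name: str, **overrides) -> PlantParams:
    """Plant parameters for a named strawberry variety.

    theta_true and k_true carry the per-variety critical soil water content
    and decline slope; the plateau-scale parameters (g_ref, growth) are the
    shared documented defaults, overridable by keyword.
    """
    key = name.lower()
    if key not in VARIETY_PRESETS:
        raise ValueError(f"unknown variety {name!r}; known: {sorted(VARIETY_PRESETS)}")
    return PlantParams(**{**VARIETY_PRESETS[key], **overrides})


def simulate_fpkm(
    n_genes: int = 2000,
    de_fraction: float = 0.10,
    fold: float = 4.0,
    seed: int = 0,
    n_reps: int = 3,
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 2.0,
    rep_log2_sd: float = 0.1,
    conditions: tuple[str, str] = ("ctrl", "stress"),
):
    """Synthetic FPKM matrix with labelled differential genes.

    Baseline abundances are log-normal (log2 mean/sd configurable; the left
    tail dips below the FPKM = 1 floor so the expression filter has work to
    do); replicate noise is log-normal with ``rep_log2_sd``. A random
    ``de_fraction`` of genes is shifted by ``fold`` in the second condition,
    alternating up/down. Returns ``(ExpressionMatrix, truth)`` where truth
    is a DataFrame with ``is_de`` and ``direction`` per gene.
    """
    from .deg import ExpressionMatrix

    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0 <= de_fraction <= 0.5:
        raise ValueError("de_fraction must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    sign = np.zeros(n_genes)
    sign[de_idx] = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    shift = sign * np.log2(fold)

    cols = {}
    for r in range(n_reps):
        cols[f"{conditions[0]}_r{r + 1}"] = 2.0 ** (base + rng.normal(0, rep_log2_sd, n_genes))
    for r in range(n_reps):
        cols[f"{conditions[1]}_r{r + 1}"] = 2.0 ** (base + shift + rng.normal(0, rep_log2_sd, n_genes))
    fpkm = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    cond_map = {s: (conditions[0] if s.startswith(conditions[0]) else conditions[1]) for s in fpkm.columns}
    truth = pd.DataFrame(
        {
            "is_de": sign != 0,
            "direction": np.where(sign > 0, "up", np.where(sign < 0, "down", "none")),
        },
        index=fpkm.index,
    )
    return ExpressionMatrix(fpkm=fpkm, conditions=cond_map), truth
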