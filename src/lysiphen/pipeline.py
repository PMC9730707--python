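"""End-to-end orchestration: simulate → traits → fits → comparisons (→ DEG).

Two entry points matter to most users. :func:`variety_recovery_experiment`
runs the reference drydown protocol for one variety — simulate replicate
pots, extract the midday response through the real trait pipeline, fit the
two-segment model per pot and aggregate — and is what the acceptance script
drives. :func:`run_full` executes the whole multi-treatment pipeline from a
:class:`RunConfig` and writes TSV/JSON reports, each stamped with the config
hash so outputs are traceable to their settings.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as _compare
from . import deg as _deg
from . import drydown as _drydown
from . import simulate as _simulate
from . import traits as _traits
from .design import PhaseDesign
from .errors import DesignError
from .timeseries import detect_irrigation_events

__all__ = [
    "RunConfig",
    "RecoveryResult",
    "variety_recovery_experiment",
    "run_traits",
    "run_full",
]

log = logging.getLogger("lysiphen")

VARIETIES = ("Hongyan", "Xiangye", "Zhangji")


@dataclass
class RunConfig:
    """Validated settings for a pipeline run (YAML-serialisable)."""

    varieties: tuple[str, ...] = VARIETIES
    treatments: dict[str, int] = field(default_factory=lambda: {"CK": 2, "WR_theta": 2, "WR_SD": 2})
    days: int = 26
    seed: int = 0
    n_pots_fit: int = 4
    midday_noise: float = 0.05
    grid_resolution: int = _drydown.DEFAULT_GRID_RESOLUTION
    min_daily_drop: float = _drydown.DEFAULT_MIN_DAILY_DROP
    deg: dict | None = None  # e.g. {"n_genes": 2000, "de_fraction": 0.1, "fold": 4}
    outdir: str = "lysiphen_run"

    def __post_init__(self) -> None:
        unknown = [v for v in self.varieties if v.lower() not in _simulate.VARIETY_PRESETS]
        if unknown:
            raise ValueError(f"unknown varieties {unknown}")
        bad = [t for t in self.treatments if t not in ("CK", "WR_theta", "WR_SD")]
        if bad:
            raise ValueError(f"unknown treatments {bad}")
        if self.days < 2:
            raise ValueError("days must be >= 2")
        if not 0 <= self.midday_noise < 1:
            raise ValueError("midday_noise is a fraction of the plateau in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "varieties" in raw:
            raw["varieties"] = tuple(raw["varieties"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["varieties"] = list(d["varieties"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class RecoveryResult:
    """Outcome of the replicate drydown protocol for one variety."""

    variety: str
    truth: _simulate.PlantParams
    a_eff: float
    fits: list[_drydown.DrydownFit]
    points: list[pd.DataFrame]
    aggregate: pd.DataFrame

    def mean(self, parameter: str) -> float:
        row = self.aggregate[self.aggregate["parameter"] == parameter]
        return float(row["mean"].iloc[0])

    @property
    def n_points_total(self) -> int:
        return int(sum(len(p) for p in self.points))


def _pot_to_points(
    sim: _simulate.SimResult,
    min_daily_drop: float,
    jump_threshold: float = 5.0,
) -> pd.DataFrame:
    """Run one simulated pot through the real trait pipeline to response points."""
    weight = detect_irrigation_events(sim.weight, jump_threshold)
    phases = _phase_design_from_truth(sim)
    traits = _traits.build_daily_traits(weight, sim.env, phases=phases)
    return _drydown.dynamic_period_points(traits, min_daily_drop=min_daily_drop)


def _phase_design_from_truth(sim: _simulate.SimResult) -> PhaseDesign:
    t = sim.truth
    first = sim.weight.timestamps[0].date()
    last = sim.weight.timestamps[-1].date() + _dt.timedelta(days=1)
    phases: dict[str, tuple[_dt.date, _dt.date]] = {}
    if t.drought_start is None:
        phases["well_irrigated"] = (first, last)
    else:
        if t.drought_start > first:
            phases["well_irrigated"] = (first, t.drought_start)
        drought_end = t.recovery_start if t.recovery_start is not None else last
        phases["progressive_drought"] = (t.drought_start, drought_end)
        if t.recovery_start is not None:
            phases["water_recovery"] = (t.recovery_start, last)
    return PhaseDesign(phases=phases)


def variety_recovery_experiment(
    variety: str,
    n_pots: int = 4,
    days: int = 26,
    midday_noise: float = 0.05,
    seed: int = 0,
    grid_resolution: int = _drydown.DEFAULT_GRID_RESOLUTION,
    min_daily_drop: float = _drydown.DEFAULT_MIN_DAILY_DROP,
) -> RecoveryResult:
    """Reference parameter-recovery protocol for one variety.

    Simulates ``n_pots`` replicate pots through a progressive drydown (one
    well-watered night, then irrigation withheld), extracts the midday
    (VWC, Tr_m,VPD) response for each pot through the trait pipeline, adds
    Gaussian noise with sd ``midday_noise`` × plateau to the normalised
    transpiration (the protocol's stated measurement noise; the balance
    itself is run noiseless so the injected noise level is exact), fits the
    two-segment model per pot and aggregates across pots.
    """
    plant = _simulate.variety_preset(variety)
    rng = np.random.default_rng(seed)
    fits: list[_drydown.DrydownFit] = []
    all_points: list[pd.DataFrame] = []
    a_eff = float("nan")
    schedule = _simulate.IrrigationSchedule(policy="none", well_days=1)
    pot_params = dataclasses.replace(_simulate.PotParams(), noise_sd=0.0)
    for p in range(n_pots):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        sim = _simulate.simulate_drydown(
            plant,
            pot=pot_params,
            schedule=schedule,
            days=days,
            seed=sim_seed,
            pot_id=f"{variety.lower()}_{p + 1}",
        )
        a_eff = sim.truth.a_eff
        pts = _pot_to_points(sim, min_daily_drop)
        noisy = pts.copy()
        nrng = np.random.default_rng(noise_seed)
        noisy["tr_m_vpd"] = np.clip(
            noisy["tr_m_vpd"] + nrng.normal(0, midday_noise * a_eff, len(noisy)), 0.0, None
        )
        all_points.append(noisy)
        fits.append(
            _drydown.fit_piecewise(noisy, grid_resolution=grid_resolution, label=noisy["pot_id"].iloc[0] if len(noisy) else "")
        )
    agg = _drydown.aggregate_replicates(fits, group=variety)
    return RecoveryResult(
        variety=variety, truth=plant, a_eff=a_eff, fits=fits, points=all_points, aggregate=agg
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# lysiphen config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _simulate_treatment_pots(config: RunConfig, variety: str, rng: np.random.Generator):
    plant = _simulate.variety_preset(variety)
    sims = []
    policies = {"CK": "ck", "WR_theta": "rewater_at_theta", "WR_SD": "rewater_at_wilting"}
    for trt, n in config.treatments.items():
        for p in range(n):
            schedule = _simulate.IrrigationSchedule(policy=policies[trt], well_days=3)
            sim = _simulate.simulate_drydown(
                plant,
                schedule=schedule,
                days=config.days,
                seed=int(rng.integers(0, 2**31 - 1)),
                pot_id=f"{variety.lower()}_{trt}_{p + 1}",
            )
            sims.append((trt, sim))
    return sims


def run_traits(config: RunConfig) -> pd.DataFrame:
    """Simulate the configured experiment and write the per-pot daily-traits table."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for variety in config.varieties:
        for trt, sim in _simulate_treatment_pots(config, variety, rng):
            weight = detect_irrigation_events(sim.weight)
            phases = _phase_design_from_truth(sim)
            df = _traits.build_daily_traits(weight, sim.env, phases=phases)
            df.insert(1, "variety", variety)
            df.insert(2, "treatment", trt)
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    _write_tsv(table, Path(config.outdir) / "daily_traits.tsv", config)
    log.info("traits: %d plant-days -> %s", len(table), Path(config.outdir) / "daily_traits.tsv")
    return table


def run_full(config: RunConfig) -> dict:
    """Traits → per-variety fits → treatment comparisons (→ optional DEG stage).

    Writes ``daily_traits.tsv``, ``drydown_fits.tsv``, ``comparisons.tsv``
    (and ``deg_calls.tsv`` if configured) under ``config.outdir`` plus a
    ``summary.json`` with per-variety (θ_cri, k, R²) and per-trait
    reductions. Deterministic for a fixed config (seed included).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash, "varieties": {}}

    rng = np.random.default_rng(config.seed)
    fit_rows = []
    cmp_rows = []
    traits_frames = []
    for variety in config.varieties:
        rec = variety_recovery_experiment(
            variety,
            n_pots=config.n_pots_fit,
            days=config.days,
            midday_noise=config.midday_noise,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid_resolution=config.grid_resolution,
            min_daily_drop=config.min_daily_drop,
        )
        summary["varieties"][variety] = {
            "theta_cri": rec.mean("theta_cri"),
            "k": rec.mean("k"),
            "r2": rec.mean("r2"),
            "n_pots": len(rec.fits),
        }
        for f in rec.fits:
            fit_rows.append(
                {
                    "variety": variety,
                    "pot": f.label,
                    "a": f.a,
                    "k": f.k,
                    "theta_cri": f.theta_cri,
                    "r2": f.r2,
                    "n": f.n_points,
                    "se_a": f.se_a,
                    "se_k": f.se_k,
                    "converged": f.converged,
                }
            )

        # treatment comparison on its own simulated cohort
        sims = _simulate_treatment_pots(config, variety, rng)
        treatments_map = {}
        frames = []
        drought_bounds = None
        for trt, sim in sims:
            weight = detect_irrigation_events(sim.weight)
            phases = _phase_design_from_truth(sim)
            if trt == "WR_SD" and "progressive_drought" in phases.phases:
                drought_bounds = phases.phases["progressive_drought"]
            df = _traits.build_daily_traits(weight, sim.env, phases=phases)
            df.insert(1, "variety", variety)
            df.insert(2, "treatment", trt)
            treatments_map[weight.pot_id] = trt
            frames.append(df)
        cohort = pd.concat(frames, ignore_index=True)
        traits_frames.append(cohort)
        if drought_bounds is not None and "CK" in config.treatments:
            design = PhaseDesign(phases={"progressive_drought": drought_bounds}, treatments=treatments_map)
            for trait in ("tr_m", "e_daily"):
                for trt in ("WR_theta", "WR_SD"):
                    if trt not in config.treatments:
                        continue
                    red = _compare.relative_reduction(
                        cohort, trait, trt, "CK", design, "progressive_drought"
                    )
                    cmp_rows.append(
                        {
                            "variety": variety,
                            "trait": trait,
                            "phase": "progressive_drought",
                            "treatment": trt,
                            "reference": "CK",
                            "pct_reduction": red,
                        }
                    )
            sub = cohort[
                (cohort["date"] >= drought_bounds[0]) & (cohort["date"] < drought_bounds[1])
            ].dropna(subset=["tr_m"])
            if sub["treatment"].nunique() >= 2 and sub["date"].nunique() >= 2:
                try:
                    tab = _compare.two_way_anova(sub["tr_m"], sub["treatment"], sub["date"])
                except DesignError as exc:  # e.g. single pot per treatment
                    log.info("ANOVA skipped for %s: %s", variety, exc)
                else:
                    summary["varieties"][variety]["anova_tr_m"] = {
                        "treatment_p": float(tab.loc["factor_a", "p"]),
                        "day_p": float(tab.loc["factor_b", "p"]),
                    }
        elif len(config.treatments) < 2:
            log.info("comparison stage skipped: fewer than two treatment groups configured")

    _write_tsv(pd.DataFrame(fit_rows), outdir / "drydown_fits.tsv", config)
    _write_tsv(pd.concat(traits_frames, ignore_index=True), outdir / "daily_traits.tsv", config)
    if cmp_rows:
        _write_tsv(pd.DataFrame(cmp_rows), outdir / "comparisons.tsv", config)
        summary["reductions"] = cmp_rows

    if config.deg:
        em, truth = _simulate.simulate_fpkm(
            n_genes=int(config.deg.get("n_genes", 2000)),
            de_fraction=float(config.deg.get("de_fraction", 0.1)),
            fold=float(config.deg.get("fold", 4.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        kept = _deg.expression_filter(em)
        calls = _deg.differential_call(em, kept)
        _write_tsv(calls.reset_index(), outdir / "deg_calls.tsv", config)
        summary["deg"] = {
            "n_genes": int(len(em.fpkm)),
            "n_kept": int(len(kept)),
            "n_deg": int(calls["is_deg"].sum()),
            "n_true_de": int(truth["is_de"].sum()),
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("summary -> %s", outdir / "summary.json")
    return summary
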