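"""Configuration, orchestration, and the end-to-end recovery experiment.

The recovery experiment is the package's own validation loop: simulate a
chamber under a configured stimulus schedule, optionally corrupt the
tracking output, run the Eulerian estimators, and compare against the
simulator's event-log ground truth.  All randomness flows from the
configured seed list; stage-specific substreams are derived
deterministically from each master seed, so identical configs give
identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import chamber_sim, fluorescence, rates
from .chamber_sim import EnvRateMap, ReporterParams, SimConfig
from .environment import EnvironmentSchedule, make_schedule
from .tracking_io import TrackingWindow

logger = logging.getLogger(__name__)

_RATE_KEYS = {
    "glucose": (True, False),
    "glucose_sorbitol": (True, True),
    "starved": (False, False),
    "starved_sorbitol": (False, True),
}


class ScheduleBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    regime: str = "constant"
    period_min: Optional[float] = None
    glucose_high_pct: float = 2.0
    sorbitol_high_M: float = 1.0
    acclimation_min: float = 60.0
    duration_min: float = 720.0
    pulse_start_min: Optional[float] = None
    pulse_length_min: Optional[float] = None

    def build(self) -> EnvironmentSchedule:
        return make_schedule(
            regime=self.regime,
            period=self.period_min,
            glucose_high=self.glucose_high_pct,
            sorbitol_high=self.sorbitol_high_M,
            acclimation=self.acclimation_min,
            total_duration=self.duration_min,
            pulse_start=self.pulse_start_min,
            pulse_length=self.pulse_length_min,
        )


class SimBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    initial_cells: int = 150
    imaging_interval_min: float = 6.0
    division_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "glucose": 0.0066,
            "glucose_sorbitol": 0.0033,
            "starved": 0.0005,
            "starved_sorbitol": 0.0002,
        }
    )
    death_rates: dict[str, float] = Field(default_factory=dict)
    division_lag_min: float = 12.0
    glycerol_gain: float = 0.02
    glycerol_glucose_factor: float = 2.0
    glycerol_decay: float = 0.01
    lysis_slope: float = 0.08
    glycerol_retention: float = 0.0
    motility_sigma_px: float = 4.0
    crowding_capacity: int = 1500
    dead_visible_frames: int = 999
    fov: str = "fov01"

    @field_validator("division_rates", "death_rates")
    @classmethod
    def _known_keys(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(_RATE_KEYS)
        if unknown:
            raise ValueError(f"unknown rate key(s): {sorted(unknown)}; valid: {sorted(_RATE_KEYS)}")
        return v

    def _map(self, d: dict[str, float], default: float = 0.0) -> EnvRateMap:
        full = {key: default for key in _RATE_KEYS.values()}
        for name, r in d.items():
            full[_RATE_KEYS[name]] = r
        return EnvRateMap(full)

    def build(self, seed: int = 0) -> SimConfig:
        return SimConfig(
            initial_cells=self.initial_cells,
            imaging_interval=self.imaging_interval_min,
            division_rate_map=self._map(self.division_rates),
            death_rate_map=self._map(self.death_rates),
            division_lag=self.division_lag_min,
            glycerol_gain=self.glycerol_gain,
            glycerol_glucose_factor=self.glycerol_glucose_factor,
            glycerol_decay=self.glycerol_decay,
            lysis_slope=self.lysis_slope,
            glycerol_retention=self.glycerol_retention,
            motility_sigma=self.motility_sigma_px,
            crowding_capacity=self.crowding_capacity,
            dead_visible_frames=self.dead_visible_frames,
            fov=self.fov,
            seed=seed,
        )


class ReporterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hog1_peak: float = 2.5
    hog1_half_life_glucose_min: float = 6.0
    hog1_half_life_starved_min: float = 45.0
    pstl1_txn_rate: float = 0.05
    pstl1_maturation_delay_min: float = 20.0
    pstl1_dilution: float = 0.005
    noise_cv: float = 0.05

    def build(self) -> ReporterParams:
        return ReporterParams(
            hog1_peak=self.hog1_peak,
            hog1_adapt_rate_glucose=np.log(2) / self.hog1_half_life_glucose_min,
            hog1_adapt_rate_starved=np.log(2) / self.hog1_half_life_starved_min,
            pstl1_txn_rate=self.pstl1_txn_rate,
            pstl1_maturation_delay=self.pstl1_maturation_delay_min,
            pstl1_dilution=self.pstl1_dilution,
            noise_cv=self.noise_cv,
        )


class CorruptionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    swap_rate: float = 0.0
    drop_rate: float = 0.0
    frame_drop_rate: float = 0.0


class EstimationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_side_px: float = 1928.0
    frame_side_px: float = 2048.0
    denominator: Literal["start", "end", "mid"] = "start"
    equal_var_ttest: bool = False
    corruption: CorruptionBlock = Field(default_factory=CorruptionBlock)

    def window(self) -> TrackingWindow:
        return TrackingWindow.centered(self.window_side_px, self.frame_side_px)


class ExperimentConfig(BaseModel):
    """Resolved configuration of one synthetic experiment."""

    model_config = ConfigDict(extra="forbid")
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    sim: SimBlock = Field(default_factory=SimBlock)
    reporters: ReporterBlock = Field(default_factory=ReporterBlock)
    estimation: EstimationBlock = Field(default_factory=EstimationBlock)
    seeds: list[int] = Field(default_factory=lambda: [1])

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % (2**31))


def run_recovery(config: ExperimentConfig) -> dict:
    """Simulate, estimate, and compare to ground truth for every seed.

    Returns a machine-readable report: per-seed true and estimated division
    and death rates, relative errors, conservation-violation counts (which
    must be zero before corruption), and corrupted-table estimates when a
    corruption block is configured.
    """
    schedule = config.schedule.build()
    window = config.estimation.window()
    corr = config.estimation.corruption
    per_seed = []
    for seed in config.seeds:
        sim_cfg = config.sim.build(seed=seed)
        table, truth = chamber_sim.simulate_chamber(sim_cfg, schedule, window=window)
        counts = rates.frame_counts(table, window)
        est_kw = dict(schedule=schedule, denominator=config.estimation.denominator)
        div = rates.mean_rate(counts, "division", **est_kw)
        dth = rates.mean_rate(counts, "death", **est_kw)
        t_true = chamber_sim.true_rates(truth, div.t0, div.t1)
        entry = {
            "seed": seed,
            "true_division_rate": t_true[0],
            "true_death_rate": t_true[1],
            "est_division_rate": div.rate,
            "est_death_rate": dth.rate,
            "est_growth_rate": rates.population_growth_rate(div, dth),
            "true_growth_rate": t_true[0] - t_true[1],
            "conservation_violations": counts.conservation_violations(),
            "n_intervals": div.n_intervals,
        }
        entry["division_rel_error"] = (
            abs(div.rate - t_true[0]) / t_true[0] if t_true[0] > 0 else None
        )
        entry["death_rel_error"] = (
            abs(dth.rate - t_true[1]) / t_true[1] if t_true[1] > 0 else None
        )
        if corr.swap_rate or corr.drop_rate or corr.frame_drop_rate:
            noisy = chamber_sim.inject_tracking_errors(
                table,
                swap_rate=corr.swap_rate,
                drop_rate=corr.drop_rate,
                frame_drop_rate=corr.frame_drop_rate,
                seed=_stage_seed(seed, "corruption"),
            )
            ncounts = rates.frame_counts(noisy, window)
            ndiv = rates.mean_rate(ncounts, "division", **est_kw)
            entry["est_division_rate_corrupted"] = ndiv.rate
            entry["corrupted_vs_clean_rel_dev"] = (
                abs(ndiv.rate - div.rate) / div.rate if div.rate > 0 else None
            )
        per_seed.append(entry)

    div_errs = [e["division_rel_error"] for e in per_seed if e["division_rel_error"] is not None]
    death_errs = [e["death_rel_error"] for e in per_seed if e["death_rel_error"] is not None]
    report = {
        "config": config.model_dump(),
        "per_seed": per_seed,
        "summary": {
            "n_seeds": len(per_seed),
            "mean_division_rel_error": float(np.mean(div_errs)) if div_errs else None,
            "mean_death_rel_error": float(np.mean(death_errs)) if death_errs else None,
            "total_conservation_violations": int(
                sum(e["conservation_violations"] for e in per_seed)
            ),
            "mean_est_division_rate": float(np.mean([e["est_division_rate"] for e in per_seed])),
            "mean_est_death_rate": float(np.mean([e["est_death_rate"] for e in per_seed])),
        },
    }
    return report


def run_demo(config: ExperimentConfig, out_dir) -> dict[str, str]:
    """Write demo figures and tables for one configured experiment.

    Produces a phase-folded division-rate profile, the population nuclear
    enrichment curve of the simulated reporter, and a per-seed rate table.
    All outputs carry a synthetic-data caption.  Returns written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = config.schedule.build()
    window = config.estimation.window()
    written: dict[str, str] = {}

    series, rows = [], []
    traces_curve = None
    for seed in config.seeds:
        sim_cfg = config.sim.build(seed=seed)
        table, truth = chamber_sim.simulate_chamber(sim_cfg, schedule, window=window)
        counts = rates.frame_counts(table, window)
        div = rates.mean_rate(counts, "division", schedule=schedule)
        dth = rates.mean_rate(counts, "death", schedule=schedule)
        rows.append(
            {
                "seed": seed,
                "division_rate": div.rate,
                "death_rate": dth.rate,
                "growth_rate": rates.population_growth_rate(div, dth),
            }
        )
        series.append(rates.interval_rates(counts, "division"))
        if traces_curve is None:
            traces = chamber_sim.simulate_reporters(truth, config.reporters.build())
            enr = fluorescence.nuclear_enrichment(traces)
            traces_curve = fluorescence.population_curve(enr, "enrichment")

    import pandas as pd

    rate_table = pd.DataFrame(rows)
    rate_path = out_dir / "rates_summary.csv"
    rate_table.to_csv(rate_path, index=False)
    written["rates_summary"] = str(rate_path)

    if schedule.is_periodic:
        prof = rates.fold_by_phase(series, schedule)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(
            prof.bins["phase_center"],
            prof.bins["mean_rate"],
            yerr=[
                prof.bins["mean_rate"] - prof.bins["ci95_low"],
                prof.bins["ci95_high"] - prof.bins["mean_rate"],
            ],
            fmt="o",
            capsize=2,
        )
        ax.axvline(prof.period / 2, ls="--", c="gray")
        ax.set_xlabel("phase within period (min)")
        ax.set_ylabel("division rate (min$^{-1}$)")
        ax.set_title(f"Phase-folded division rate, {schedule.regime.value} (synthetic data)")
        fig.tight_layout()
        p = out_dir / "phase_profile.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["phase_profile"] = str(p)

    if traces_curve is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(traces_curve["time"], traces_curve["mean"])
        ax.fill_between(
            traces_curve["time"], traces_curve["ci95_low"], traces_curve["ci95_high"], alpha=0.3
        )
        ax.set_xlabel("time (min)")
        ax.set_ylabel("nuclear enrichment")
        ax.set_title("Mean nuclear enrichment (synthetic reporter)")
        fig.tight_layout()
        p = out_dir / "enrichment_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["enrichment_curve"] = str(p)

    (out_dir / "resolved_config.yaml").write_text(config.resolved_yaml())
    written["resolved_config"] = str(out_dir / "resolved_config.yaml")
    return written


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
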