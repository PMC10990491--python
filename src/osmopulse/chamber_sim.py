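"""Agent-based generator of synthetic nucleus-tracking tables.

The simulator emulates the statistical structure of the tracking output of
a yeast microfluidic chamber imaged every 6 minutes: exponential per-capita
division with an environment-dependent rate (applied after a lag, since
growth arrest follows glucose removal with a delay), random-walk motility
producing boundary crossings of the fixed tracking window, crowding-driven
washout of cells near the chamber edge, dead nuclei that remain detectable
and motionless for hours, and cell lysis clustered within minutes of
hypo-osmotic down-shifts.

Lysis follows an explicit synthetic osmolyte model, not a fit to any
measured curve: cells accumulate glycerol while sorbitol is present
(faster when glucose is also present, since glycolytic flux feeds glycerol
synthesis), glycerol decays by export, and at each sorbitol removal every
living cell lyses with probability ``min(1, lysis_slope * glycerol)``.
Phasing sorbitol with glucose (alternating-stress style) therefore loads
cells with more glycerol at the moment of the down-shift than phasing
sorbitol with starvation (in-phase style) — the asymmetry is emergent from
the phasing, not hard-coded.

Everything is deterministic given (config, schedule, seed): identical
inputs give identical tables and event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .environment import EnvState, EnvironmentSchedule
from .tracking_io import COLUMNS, TrackingWindow, _normalize


@dataclass(frozen=True)
class EnvRateMap:
    """Per-capita rate (min^-1) as a function of medium composition.

    Keyed on glucose/sorbitol *presence*; the quantification pipeline only
    distinguishes on/off states of each compound.
    """

    rates: Mapping[tuple[bool, bool], float]  # (has_glucose, has_sorbitol) -> rate

    def __post_init__(self) -> None:
        for k, v in self.rates.items():
            if v < 0:
                raise ValueError(f"negative rate {v} for {k}")

    def rate_for(self, env: EnvState) -> float:
        key = (env.has_glucose, env.has_sorbitol)
        if key not in self.rates:
            raise KeyError(f"no rate configured for glucose={key[0]}, sorbitol={key[1]}")
        return self.rates[key]

    @classmethod
    def constant(cls, rate: float) -> "EnvRateMap":
        return cls({(g, s): rate for g in (True, False) for s in (True, False)})

    @classmethod
    def from_table(cls, table: Mapping[tuple[float, float], float]) -> "EnvRateMap":
        """Build from a {(glucose, sorbitol): rate} concentration table."""
        return cls({(g > 0, s > 0): r for (g, s), r in table.items()})


#: division rates echoing the observed range: fast growth on glucose,
#: slowed by sorbitol, near-arrest under starvation
DEFAULT_DIVISION_MAP = EnvRateMap(
    {
        (True, False): 0.0066,
        (True, True): 0.0033,
        (False, False): 0.0005,
        (False, True): 0.0002,
    }
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic chamber run.

    Spatial units are pixels of the 2048x2048 field of view; time units are
    minutes.  ``division_lag`` delays the effect of a medium change on the
    division rate.  The glycerol parameters are in arbitrary osmolyte units;
    see the module docstring for the lysis model.
    """

    chamber_size: tuple[float, float] = (2048.0, 2048.0)
    initial_cells: int = 150
    imaging_interval: float = 6.0
    division_rate_map: EnvRateMap = field(default_factory=lambda: DEFAULT_DIVISION_MAP)
    death_rate_map: EnvRateMap = field(default_factory=lambda: EnvRateMap.constant(0.0))
    division_lag: float = 12.0
    glycerol_gain: float = 0.02  # a.u./min while sorbitol present
    glycerol_glucose_factor: float = 2.0  # extra gain factor when glucose present
    glycerol_decay: float = 0.01  # min^-1
    lysis_slope: float = 0.08  # lysis probability per glycerol unit at down-shift
    glycerol_retention: float = 0.0  # fraction kept after a down-shift (export channel opens)
    motility_sigma: float = 4.0  # px per frame
    crowding_capacity: int = 1500
    dead_visible_frames: int = 999
    nucleus_size_px: float = 90.0
    daughter_offset_px: float = 12.0
    fov: str = "fov01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_cells < 1:
            raise ValueError("initial_cells must be >= 1")
        if self.imaging_interval <= 0:
            raise ValueError("imaging_interval must be > 0")
        if self.crowding_capacity < self.initial_cells:
            raise ValueError("crowding_capacity must be >= initial_cells")
        if self.motility_sigma < 0 or self.glycerol_gain < 0 or self.glycerol_decay < 0:
            raise ValueError("rates and sigmas must be non-negative")


@dataclass(frozen=True)
class ReporterParams:
    """Synthetic kinetics of the two fluorescent readouts.

    Hog1 nuclear enrichment jumps to ``hog1_peak`` at each hyperosmotic
    shock and relaxes exponentially toward 1; adaptation is fast when
    glucose is present and much slower under starvation (osmoregulation
    requires glycolytic flux).  The stress-responsive transcriptional
    reporter integrates transcription gated on nuclear Hog1 *and* glucose
    presence, with a maturation delay and dilution by growth.  All values
    are qualitative synthetic defaults, not fitted estimates.
    """

    hog1_peak: float = 2.5
    hog1_adapt_rate_glucose: float = math.log(2) / 6.0  # half-life 6 min
    hog1_adapt_rate_starved: float = math.log(2) / 45.0  # half-life 45 min
    hog1_release_rate: float = math.log(2) / 4.0  # return on stress removal
    hog1_threshold: float = 1.5  # enrichment gating transcription
    pstl1_txn_rate: float = 0.05  # fold-change units/min while active
    pstl1_maturation_delay: float = 20.0  # min
    pstl1_dilution: float = 0.005  # min^-1
    noise_cv: float = 0.05
    baseline_fluor: float = 100.0  # a.u.
    cell_area_px: float = 500.0
    nucleus_area_px: float = 60.0

    def __post_init__(self) -> None:
        if self.hog1_adapt_rate_glucose <= self.hog1_adapt_rate_starved:
            raise ValueError("adaptation must be faster with glucose than without")
        if self.hog1_peak <= 1:
            raise ValueError("hog1_peak must exceed 1")


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``events``: one row per event — time, type (division / death /
    window_entry / window_exit / washout), object_id, parent_id,
    in_window (for division: parent window-resident at the previous frame;
    for death: nucleus inside the window).
    ``window_counts``: true living-in-window count per frame.
    ``cell_states``: per frame and living cell, the hidden glycerol level.
    """

    events: pd.DataFrame
    window_counts: pd.DataFrame
    cell_states: pd.DataFrame
    config: SimConfig
    schedule: EnvironmentSchedule

    def birth_times(self) -> dict[int, float]:
        """First-visible time per object id (initial cells at t=0)."""
        g = self.cell_states.groupby("object_id")["time"].min()
        return {int(k): float(v) for k, v in g.items()}


def _glycerol_step(g, env: EnvState, dt: float, cfg: SimConfig):
    """Exact update of dg/dt = P - decay*g over dt with constant env."""
    production = cfg.glycerol_gain * (1.0 if env.has_sorbitol else 0.0) * (
        1.0 + (cfg.glycerol_glucose_factor if env.has_glucose else 0.0)
    )
    if cfg.glycerol_decay > 0:
        g_inf = production / cfg.glycerol_decay
        return g_inf + (g - g_inf) * math.exp(-cfg.glycerol_decay * dt)
    return g + production * dt


def simulate_chamber(
    config: SimConfig,
    schedule: EnvironmentSchedule,
    seed: int | None = None,
    window: TrackingWindow | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Run the agent-based chamber and emit (tracking table, ground truth).

    One record per visible nucleus per frame at the imaging interval.
    Daughters appear adjacent to their mother with ``parent_id`` set; lysed
    cells are flagged dead from their lysis frame and their nuclei persist
    motionless for ``dead_visible_frames``.  ``window`` only affects truth
    bookkeeping (entry/exit logging and the resident counts used by
    :func:`true_rates`), never the dynamics.
    """
    if schedule.total_duration < config.imaging_interval:
        raise ValueError("schedule must span at least one imaging interval")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    window = window or TrackingWindow()
    W, H = config.chamber_size
    dt = config.imaging_interval
    n_frames = int(math.floor(schedule.total_duration / dt)) + 1

    # state arrays (python lists of per-cell scalars kept in numpy arrays)
    n0 = config.initial_cells
    x = rng.uniform(0, W, n0)
    y = rng.uniform(0, H, n0)
    ids = np.arange(n0, dtype=np.int64)
    parent = np.full(n0, -1, dtype=np.int64)
    alive = np.ones(n0, dtype=bool)
    present = np.ones(n0, dtype=bool)  # still in the field (not washed out)
    glycerol = np.zeros(n0)
    death_frame = np.full(n0, -1, dtype=np.int64)
    next_id = n0

    table_parts: list[pd.DataFrame] = []
    state_parts: list[pd.DataFrame] = []
    events: list[tuple] = []  # (time, type, object_id, parent_id, in_window)
    window_counts: list[tuple] = []

    downshifts = schedule.sorbitol_downshifts()

    def emit(frame: int, t: float) -> None:
        visible = present & (alive | (frame - death_frame <= config.dead_visible_frames))
        idx = np.where(visible)[0]
        if len(idx) == 0:
            return
        table_parts.append(
            pd.DataFrame(
                {
                    "fov": config.fov,
                    "frame": frame,
                    "time": t,
                    "object_id": ids[idx],
                    "parent_id": pd.array(
                        [None if parent[i] < 0 else int(parent[i]) for i in idx],
                        dtype="Int64",
                    ),
                    "x": x[idx],
                    "y": y[idx],
                    "size": config.nucleus_size_px
                    * (1 + 0.05 * rng.standard_normal(len(idx))),
                    "dead": ~alive[idx],
                }
            )
        )
        live_idx = np.where(present & alive)[0]
        inside = window.contains(x[live_idx], y[live_idx])
        window_counts.append((frame, t, int(inside.sum())))
        state_parts.append(
            pd.DataFrame(
                {
                    "frame": frame,
                    "time": t,
                    "object_id": ids[live_idx],
                    "glycerol": glycerol[live_idx],
                    "in_window": inside,
                }
            )
        )

    for frame in range(n_frames):
        t0 = frame * dt
        emit(frame, t0)
        if frame == n_frames - 1:
            break
        t1 = (frame + 1) * dt

        live = present & alive
        inside_before = window.contains(x, y) & live

        # --- division: environment seen `division_lag` minutes ago
        env_div = schedule.env_at(max(0.0, t0 - config.division_lag))
        r_div = config.division_rate_map.rate_for(env_div)
        p_div = 1.0 - math.exp(-r_div * dt)
        dividing = live & (rng.random(len(ids)) < p_div)

        # --- spontaneous death (no lag)
        env_now = schedule.env_at(t0)
        r_death = config.death_rate_map.rate_for(env_now)
        p_death = 1.0 - math.exp(-r_death * dt)
        dying = live & ~dividing & (rng.random(len(ids)) < p_death)

        # --- glycerol dynamics and lysis at hypo-osmotic down-shifts
        edges = [e for e in downshifts if t0 < e <= t1]
        seg_start = t0
        for edge in edges:
            env_seg = schedule.env_at(seg_start)
            prod = config.glycerol_gain * (1.0 if env_seg.has_sorbitol else 0.0) * (
                1.0 + (config.glycerol_glucose_factor if env_seg.has_glucose else 0.0)
            )
            if config.glycerol_decay > 0:
                g_inf = prod / config.glycerol_decay
                glycerol[live] = g_inf + (glycerol[live] - g_inf) * math.exp(
                    -config.glycerol_decay * (edge - seg_start)
                )
            else:
                glycerol[live] = glycerol[live] + prod * (edge - seg_start)
            p_lysis = np.minimum(1.0, config.lysis_slope * glycerol)
            lysing = live & ~dying & (rng.random(len(ids)) < p_lysis)
            dying |= lysing
            # survivors dump glycerol on the hypo-osmotic shock
            glycerol[live] *= config.glycerol_retention
            seg_start = edge
        env_seg = schedule.env_at(seg_start)
        if seg_start < t1:
            # no per-cell variation within a segment: vectorized exact update
            prod = config.glycerol_gain * (1.0 if env_seg.has_sorbitol else 0.0) * (
                1.0 + (config.glycerol_glucose_factor if env_seg.has_glucose else 0.0)
            )
            if config.glycerol_decay > 0:
                g_inf = prod / config.glycerol_decay
                glycerol[live] = g_inf + (glycerol[live] - g_inf) * math.exp(
                    -config.glycerol_decay * (t1 - seg_start)
                )
            else:
                glycerol[live] = glycerol[live] + prod * (t1 - seg_start)

        # apply deaths: nucleus freezes where it was at t0
        for i in np.where(dying)[0]:
            alive[i] = False
            death_frame[i] = frame + 1
            events.append(
                (t1, "death", int(ids[i]), None, bool(window.contains(x[i], y[i])))
            )

        # --- motility of surviving cells (reflected random walk)
        live = present & alive
        nx = x + np.where(live, rng.normal(0, config.motility_sigma, len(ids)), 0.0)
        ny = y + np.where(live, rng.normal(0, config.motility_sigma, len(ids)), 0.0)
        x = np.abs(nx) if config.motility_sigma > 0 else nx
        x = np.where(x > W, 2 * W - x, x)
        y = np.abs(ny) if config.motility_sigma > 0 else ny
        y = np.where(y > H, 2 * H - y, y)

        # --- births
        div_idx = np.where(dividing & alive)[0]  # lysis during the interval cancels
        if len(div_idx):
            theta = rng.uniform(0, 2 * math.pi, len(div_idx))
            bx = np.clip(x[div_idx] + config.daughter_offset_px * np.cos(theta), 0, W)
            by = np.clip(y[div_idx] + config.daughter_offset_px * np.sin(theta), 0, H)
            new_ids = np.arange(next_id, next_id + len(div_idx), dtype=np.int64)
            next_id += len(div_idx)
            for j, i in enumerate(div_idx):
                events.append(
                    (t1, "division", int(new_ids[j]), int(ids[i]), bool(inside_before[i]))
                )
            x = np.concatenate([x, bx])
            y = np.concatenate([y, by])
            ids = np.concatenate([ids, new_ids])
            parent = np.concatenate([parent, ids[div_idx]])
            alive = np.concatenate([alive, np.ones(len(div_idx), dtype=bool)])
            present = np.concatenate([present, np.ones(len(div_idx), dtype=bool)])
            glycerol = np.concatenate([glycerol, glycerol[div_idx]])
            death_frame = np.concatenate([death_frame, np.full(len(div_idx), -1, dtype=np.int64)])

        # --- crowding-driven washout: excess cells nearest the chamber edge leave
        live_idx = np.where(present & alive)[0]
        excess = len(live_idx) - config.crowding_capacity
        if excess > 0:
            edge_dist = np.minimum.reduce(
                [x[live_idx], W - x[live_idx], y[live_idx], H - y[live_idx]]
            )
            out = live_idx[np.argsort(edge_dist)[:excess]]
            for i in out:
                present[i] = False
                if i < len(inside_before) and inside_before[i]:
                    events.append((t1, "washout", int(ids[i]), None, True))
                else:
                    events.append((t1, "washout", int(ids[i]), None, False))

        # --- window entry/exit bookkeeping for surviving pre-existing cells
        n_old = len(inside_before)
        live_old = (present & alive)[:n_old]
        inside_after = window.contains(x[:n_old], y[:n_old]) & live_old
        for i in np.where(inside_after & ~inside_before & live_old)[0]:
            events.append((t1, "window_entry", int(ids[i]), None, True))
        for i in np.where(inside_before & ~inside_after & live_old)[0]:
            events.append((t1, "window_exit", int(ids[i]), None, False))

    table = _normalize(pd.concat(table_parts, ignore_index=True)[COLUMNS])
    truth = SimTruth(
        events=pd.DataFrame(
            events, columns=["time", "type", "object_id", "parent_id", "in_window"]
        ),
        window_counts=pd.DataFrame(window_counts, columns=["frame", "time", "n_living_window"]),
        cell_states=pd.concat(state_parts, ignore_index=True),
        config=config,
        schedule=schedule,
    )
    return table, truth


def true_rates(truth: SimTruth, t0: float, t1: float) -> tuple[float, float]:
    """Ground-truth per-capita rates over [t0, t1] from the event log.

    Division rate = window-resident division events in (t0, t1] divided by
    the living-cell minutes spent in the window over the same span (frame
    counts times the imaging interval); death rate analogous.
    """
    if t1 <= t0:
        raise ValueError("empty interval")
    dt = truth.config.imaging_interval
    wc = truth.window_counts
    used = wc[(wc["time"] >= t0 - 1e-9) & (wc["time"] <= t1 - dt + 1e-9)]
    cell_minutes = float(used["n_living_window"].sum()) * dt
    if cell_minutes == 0:
        return (0.0, 0.0)
    ev = truth.events
    sel = (ev["time"] > t0 + 1e-9) & (ev["time"] <= t1 + 1e-9) & ev["in_window"]
    n_div = int(((ev["type"] == "division") & sel).sum())
    n_death = int(((ev["type"] == "death") & sel).sum())
    return (n_div / cell_minutes, n_death / cell_minutes)


def inject_tracking_errors(
    table: pd.DataFrame,
    swap_rate: float = 0.0,
    drop_rate: float = 0.0,
    frame_drop_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Corrupt a tracking table the way real segmentation/tracking fails.

    Per frame, each object swaps its identity with its nearest spatial
    neighbour with probability ``swap_rate`` (label confusion between
    proximate nuclei); each detection is deleted with probability
    ``drop_rate``; each whole frame is removed with probability
    ``frame_drop_rate`` (out-of-focus exclusion).  Surviving frames keep
    their original timestamps.  Deterministic per seed.
    """
    for name, r in (("swap_rate", swap_rate), ("drop_rate", drop_rate),
                    ("frame_drop_rate", frame_drop_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = _normalize(table)

    # whole-frame drops
    frames = np.sort(df["frame"].unique())
    keep_frames = frames[rng.random(len(frames)) >= frame_drop_rate]
    df = df[df["frame"].isin(keep_frames)].reset_index(drop=True)

    # identity swaps between nearest neighbours within a frame
    if swap_rate > 0:
        oid = df["object_id"].to_numpy().copy()
        for (_, _), g in df.groupby(["fov", "frame"], sort=True):
            if len(g) < 2:
                continue
            pick = np.where(rng.random(len(g)) < swap_rate)[0]
            if len(pick) == 0:
                continue
            gx = g["x"].to_numpy()
            gy = g["y"].to_numpy()
            for a in pick:
                d2 = (gx - gx[a]) ** 2 + (gy - gy[a]) ** 2
                d2[a] = np.inf
                b = int(np.argmin(d2))
                ia, ib = g.index[a], g.index[b]
                oid[ia], oid[ib] = oid[ib], oid[ia]
        df["object_id"] = oid

    # individual detection drops
    if drop_rate > 0:
        df = df[rng.random(len(df)) >= drop_rate].reset_index(drop=True)

    # swaps can duplicate (frame, id) only if an id was swapped twice; the
    # swap above is an exchange so uniqueness is preserved
    return df.sort_values(["fov", "frame", "object_id"], kind="stable").reset_index(drop=True)


def simulate_reporters(
    truth: SimTruth,
    params: ReporterParams | None = None,
    schedule: EnvironmentSchedule | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthesize per-cell fluorescence traces from a simulation's truth.

    Returns a cell-trace table (fov, object_id, time, cell_mean_fluor,
    cell_area, nucleus_mean_fluor, nucleus_area).  Nuclear enrichment
    follows the jump-decay Hog1 model and the whole-cell signal integrates
    the gated transcription model, both shared across cells up to
    multiplicative lognormal measurement noise.
    """
    params = params or ReporterParams()
    if schedule is None:
        schedule = truth.schedule
    elif schedule != truth.schedule:
        raise ValueError("schedule does not match the one used for simulation")
    rng = np.random.default_rng(truth.config.seed + 7919 if seed is None else seed)

    times = np.sort(truth.window_counts["time"].unique())
    h = _hog1_path(schedule, times, params)
    m = _reporter_path(schedule, times, params, h_fn_times=times, h_values=h)

    st = truth.cell_states
    t_index = {t: i for i, t in enumerate(times)}
    rows = st[["object_id", "time"]].copy()
    ti = rows["time"].map(t_index).to_numpy()
    n = len(rows)
    sigma = math.sqrt(math.log(1 + params.noise_cv**2))
    noise_cell = np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    noise_nuc = np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    cell_mean = params.baseline_fluor * (1.0 + m[ti]) * noise_cell
    nucleus_mean = cell_mean * h[ti] * noise_nuc
    return pd.DataFrame(
        {
            "fov": truth.config.fov,
            "object_id": rows["object_id"].to_numpy(),
            "time": rows["time"].to_numpy(),
            "cell_mean_fluor": cell_mean,
            "cell_area": params.cell_area_px,
            "nucleus_mean_fluor": nucleus_mean,
            "nucleus_area": params.nucleus_area_px,
        }
    )


def _hog1_path(schedule: EnvironmentSchedule, times: np.ndarray, params: ReporterParams) -> np.ndarray:
    """Deterministic nuclear-enrichment trajectory sampled at ``times``.

    Jumps to ``hog1_peak`` at each hyperosmotic up-shift; relaxes toward 1
    at the glucose-dependent adaptation rate while stress persists and at
    ``hog1_release_rate`` once stress is released.
    """
    ups = set(schedule.sorbitol_upshifts())
    edges = sorted(set(schedule.transition_times()) | {0.0, schedule.total_duration})
    if edges[-1] < schedule.total_duration:
        edges.append(schedule.total_duration)
    out = np.empty(len(times))
    times = np.asarray(times, dtype=float)
    h = 1.0
    for a, b in zip(edges[:-1], edges[1:]):
        if a in ups:
            h = params.hog1_peak
        env = schedule.env_at(a)
        if env.has_sorbitol:
            k_rate = (
                params.hog1_adapt_rate_glucose if env.has_glucose else params.hog1_adapt_rate_starved
            )
        else:
            k_rate = params.hog1_release_rate
        last = b >= schedule.total_duration - 1e-9
        sel = (times >= a - 1e-9) & ((times < b - 1e-9) | (last & (times <= b + 1e-9)))
        out[sel] = 1.0 + (h - 1.0) * np.exp(-k_rate * (times[sel] - a))
        h = 1.0 + (h - 1.0) * math.exp(-k_rate * (b - a))
    return out


def _reporter_path(
    schedule: EnvironmentSchedule,
    times: np.ndarray,
    params: ReporterParams,
    h_fn_times: np.ndarray,
    h_values: np.ndarray,
    grid_dt: float = 1.0,
) -> np.ndarray:
    """Gated-integration trajectory of the transcriptional reporter.

    dm/dt = txn_rate * [Hog1 nuclear AND glucose present, delay ago] -
    dilution * m, integrated on a fine grid and sampled at ``times``.
    """
    t_end = float(times[-1])
    grid = np.arange(0.0, t_end + grid_dt, grid_dt)
    h_grid = np.interp(grid, h_fn_times, h_values)
    m = np.zeros(len(grid))
    for i in range(1, len(grid)):
        t_eff = grid[i - 1] - params.pstl1_maturation_delay
        if t_eff >= 0:
            h_eff = float(np.interp(t_eff, grid, h_grid))
            env_eff = schedule.env_at(t_eff)
            active = h_eff > params.hog1_threshold and env_eff.has_glucose
        else:
            active = False
        dm = (params.pstl1_txn_rate if active else 0.0) - params.pstl1_dilution * m[i - 1]
        m[i] = max(0.0, m[i - 1] + dm * grid_dt)
    return np.interp(times, grid, m)
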