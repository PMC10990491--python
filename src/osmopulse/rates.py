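"""Eulerian per-capita division and death rate estimation.

Rates are measured inside a fixed tracking window (default 1928x1928 px
centered in the 2048x2048 field) rather than by following lineages, which
makes the estimate robust to occasional tracking errors and to crowding.
Between consecutive frames t and t+1 the living-nucleus count in the window
obeys the conservation relation

    N_window(t+1) - N_window(t) = N_new(t) + N_in(t) - N_out(t) - N_death_removed(t)

where N_new counts divisions inside the window, N_in/N_out boundary
crossings by living nuclei, and N_death_removed nuclei newly excluded from
the living count.  The per-capita division rate over [t0, t1] is the OLS
slope of the cumulative sum of N_new(t)/N_window(t) against time; the death
rate is the same construction on N_death(t).  Only living nuclei enter the
counts and the denominator.

Classification of a nucleus first seen at frame t+1 inside the window:
it is a division (N_new) only when its parent id is set and the parent was
a living window resident at frame t; otherwise it counts as an entry
(N_in), and an unparented first appearance in the window interior is
additionally logged as an anomaly.  This rule keeps the conservation
identity exact on clean tables and degrades conservatively on noisy ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .environment import EnvironmentSchedule
from .tracking_io import TrackingWindow, _normalize

logger = logging.getLogger(__name__)

EventType = Literal["division", "death"]

#: margin (px) inside the window boundary beyond which an unparented first
#: appearance is considered "interior" and logged as an anomaly
INTERIOR_MARGIN = 40.0


@dataclass
class FrameCountsSeries:
    """Per-interval window bookkeeping for one field of view."""

    data: pd.DataFrame  # t_start, t_end, N_window_start, N_window_end,
    #                     N_new, N_in, N_out, N_death, N_death_removed
    fov: str = ""
    n_anomalies: int = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def interval(self) -> float:
        """Modal sampling interval in minutes."""
        d = self.data["t_end"] - self.data["t_start"]
        return float(d.mode().iloc[0])

    def conservation_violations(self) -> int:
        d = self.data
        lhs = d["N_window_end"] - d["N_window_start"]
        rhs = d["N_new"] + d["N_in"] - d["N_out"] - d["N_death_removed"]
        return int((lhs != rhs).sum())


@dataclass
class RateEstimate:
    """Slope-based per-capita rate with regression diagnostics."""

    rate: float  # min^-1
    intercept: float
    stderr: float
    n_intervals: int
    t0: float
    t1: float
    event_type: EventType
    n_skipped: int = 0  # zero-denominator intervals skipped


@dataclass
class PhaseProfile:
    """Phase-folded rate profile over one fluctuation period."""

    period: float
    bins: pd.DataFrame  # phase_center, mean_rate, ci95_low, ci95_high, n_obs
    half_period_means: tuple[float, float]  # (first half, second half)
    half_period_ci95: tuple[tuple[float, float], tuple[float, float]] = field(
        default=((math.nan, math.nan), (math.nan, math.nan))
    )


def frame_counts(
    table: pd.DataFrame,
    window: TrackingWindow | None = None,
) -> FrameCountsSeries:
    """Count window residents, divisions, crossings and deaths per interval.

    The table must hold a single field of view.  Consecutive intervals are
    defined by frame order after any frame drops; interval times come from
    the ``time`` column, not the frame index.
    """
    if len(table) == 0:
        raise ValueError("empty input table")
    window = window or TrackingWindow()
    df = _normalize(table)
    fovs = df["fov"].unique()
    if len(fovs) > 1:
        raise ValueError(f"frame_counts expects one fov, got {list(fovs)}")
    frames = np.sort(df["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need at least two frames to form an interval")

    df["inside"] = window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    # first appearance ever, not "absent from the previous frame": a track
    # with a dropped detection must not be re-counted as a division
    first_frame = df.groupby("object_id")["frame"].min()
    by_frame = {f: g.set_index("object_id") for f, g in df.groupby("frame", sort=True)}

    rows = []
    n_anom = 0
    for f0, f1 in zip(frames[:-1], frames[1:]):
        s0, s1 = by_frame[f0], by_frame[f1]
        live0 = s0.index[(~s0["dead"]) & s0["inside"]]
        live1 = s1.index[(~s1["dead"]) & s1["inside"]]
        set0, set1 = set(live0), set(live1)

        n_new = n_in = n_out = n_death_removed = 0
        # gains: living in window at f1 but not at f0
        for oid in set1 - set0:
            parent = s1.at[oid, "parent_id"]
            first_seen = first_frame[oid] == f1
            if (
                first_seen
                and parent is not pd.NA
                and not pd.isna(parent)
                and parent in set0
            ):
                n_new += 1
            else:
                n_in += 1
                if first_seen and (parent is pd.NA or pd.isna(parent)):
                    x, y = s1.at[oid, "x"], s1.at[oid, "y"]
                    interior = (
                        x >= window.x_min + INTERIOR_MARGIN
                        and x < window.x_max - INTERIOR_MARGIN
                        and y >= window.y_min + INTERIOR_MARGIN
                        and y < window.y_max - INTERIOR_MARGIN
                    )
                    if interior:
                        n_anom += 1
        # losses: living in window at f0 but not at f1
        for oid in set0 - set1:
            if oid in s1.index and bool(s1.at[oid, "dead"]):
                n_death_removed += 1
            else:
                n_out += 1
        # death events: newly dead inside the window at f1
        dead1 = s1.index[s1["dead"] & s1["inside"]]
        prev_dead = s0["dead"].reindex(dead1).eq(True).to_numpy()
        n_death = int((~prev_dead).sum())

        rows.append(
            {
                "t_start": float(s0["time"].iloc[0]),
                "t_end": float(s1["time"].iloc[0]),
                "N_window_start": len(set0),
                "N_window_end": len(set1),
                "N_new": n_new,
                "N_in": n_in,
                "N_out": n_out,
                "N_death": n_death,
                "N_death_removed": n_death_removed,
            }
        )
    if n_anom:
        logger.info("fov %s: %d unparented interior appearance(s) counted as N_in", fovs[0], n_anom)
    return FrameCountsSeries(pd.DataFrame(rows), fov=str(fovs[0]), n_anomalies=n_anom)


def _select_intervals(
    counts: FrameCountsSeries,
    t0: float | None,
    t1: float | None,
    schedule: EnvironmentSchedule | None,
) -> pd.DataFrame:
    d = counts.data
    lo = d["t_start"].min() if t0 is None else t0
    hi = d["t_end"].max() if t1 is None else t1
    if schedule is not None:
        lo = max(lo, schedule.acclimation)
        if schedule.is_periodic:
            hi = min(hi, schedule.analysis_end())
    return d[(d["t_start"] >= lo - 1e-9) & (d["t_end"] <= hi + 1e-9)]


def mean_rate(
    counts: FrameCountsSeries,
    event_type: EventType = "division",
    t0: float | None = None,
    t1: float | None = None,
    schedule: EnvironmentSchedule | None = None,
    denominator: Literal["start", "end", "mid"] = "start",
    min_intervals: int = 3,
) -> RateEstimate:
    """Average per-capita rate over [t0, t1] from the cumulative-sum slope.

    The cumulative sum of N_event/N_window over the selected intervals is
    regressed (OLS, free intercept) on interval end time; the slope is the
    rate in min^-1.  When a periodic ``schedule`` is given, the acclimation
    hour and any incomplete final fluctuation period are excluded.
    Intervals with a zero denominator are skipped and reported.
    """
    col = {"division": "N_new", "death": "N_death"}[event_type]
    d = _select_intervals(counts, t0, t1, schedule)
    if denominator == "start":
        denom = d["N_window_start"].to_numpy(dtype=float)
    elif denominator == "end":
        denom = d["N_window_end"].to_numpy(dtype=float)
    else:
        denom = (d["N_window_start"].to_numpy() + d["N_window_end"].to_numpy()) / 2.0
    ok = denom > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("mean_rate: skipped %d zero-denominator interval(s)", n_skipped)
    d = d[ok]
    denom = denom[ok]
    if len(d) < min_intervals:
        raise ValueError(f"need >= {min_intervals} usable intervals, have {len(d)}")
    y = np.cumsum(d[col].to_numpy(dtype=float) / denom)
    x = d["t_end"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    return RateEstimate(
        rate=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        n_intervals=len(d),
        t0=float(d["t_start"].min()),
        t1=float(d["t_end"].max()),
        event_type=event_type,
        n_skipped=n_skipped,
    )


def interval_rates(
    counts: FrameCountsSeries,
    event_type: EventType = "division",
    denominator: Literal["start", "end", "mid"] = "start",
) -> pd.DataFrame:
    """Per-interval normalized event rate N_event/(N_window * dt), min^-1.

    One observation per imaging interval, timestamped at the interval start;
    this is the finest-grained rate series and the input to phase folding.
    Zero-denominator intervals yield NaN.
    """
    col = {"division": "N_new", "death": "N_death"}[event_type]
    d = counts.data
    if denominator == "start":
        denom = d["N_window_start"].to_numpy(dtype=float)
    elif denominator == "end":
        denom = d["N_window_end"].to_numpy(dtype=float)
    else:
        denom = (d["N_window_start"].to_numpy() + d["N_window_end"].to_numpy()) / 2.0
    dt = (d["t_end"] - d["t_start"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(denom > 0, d[col].to_numpy(dtype=float) / (denom * dt), np.nan)
    return pd.DataFrame({"time": d["t_start"].to_numpy(dtype=float), "rate": rate})


def instantaneous_rates(
    counts: FrameCountsSeries,
    event_type: EventType = "division",
    width: float = 36.0,
    step: float = 6.0,
    denominator: Literal["start", "end", "mid"] = "start",
) -> pd.DataFrame:
    """'Instantaneous' rate: the mean-rate slope over a sliding window.

    Every ``step`` minutes, the cumulative-sum regression is applied to the
    intervals inside a centered window of ``width`` minutes (default: 36-min
    windows every 6 min).  Windows truncated at the series edges are kept
    and flagged.  Returns columns time, rate, n_intervals, truncated.
    """
    d = counts.data
    span = d["t_end"].max() - d["t_start"].min()
    if span < width:
        raise ValueError(f"series span {span} min shorter than window width {width}")
    t_lo, t_hi = d["t_start"].min(), d["t_end"].max()
    centers = np.arange(t_lo + step / 2, t_hi, step)
    rows = []
    for c in centers:
        lo, hi = c - width / 2, c + width / 2
        truncated = lo < t_lo - 1e-9 or hi > t_hi + 1e-9
        sub = d[(d["t_start"] >= lo - 1e-9) & (d["t_end"] <= hi + 1e-9)]
        if len(sub) < 3:
            rows.append({"time": c, "rate": np.nan, "n_intervals": len(sub), "truncated": True})
            continue
        est = mean_rate(
            FrameCountsSeries(sub, fov=counts.fov),
            event_type=event_type,
            denominator=denominator,
        )
        rows.append(
            {"time": c, "rate": est.rate, "n_intervals": est.n_intervals, "truncated": truncated}
        )
    return pd.DataFrame(rows)


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return (math.nan, math.nan)
    half = stats.t.ppf((1 + level) / 2, n - 1) * float(np.std(values, ddof=1)) / math.sqrt(n)
    return (m - half, m + half)


def fold_by_phase(
    series_list: Sequence[pd.DataFrame],
    schedule: EnvironmentSchedule,
    bin_width: float = 6.0,
) -> PhaseProfile:
    """Fold per-FOV rate series over the fluctuation period.

    Each observation (one rate at one time, from one FOV) is assigned to the
    phase bin of its timestamp; bins have ``bin_width`` minutes (default the
    imaging interval).  Per-bin mean and t-based 95% CI are taken across all
    observations in the bin, pooling FOVs and periods; half-period means
    pool all observations in each half.
    """
    if not schedule.is_periodic:
        raise ValueError("phase folding requires a periodic schedule")
    T = float(schedule.period)
    obs = []
    grid = None
    for s in series_list:
        t = np.asarray(s["time"], dtype=float)
        g = np.round(np.diff(np.sort(t)), 6)
        g = g[g > 0]
        this_grid = float(np.min(g)) if len(g) else None
        if grid is None:
            grid = this_grid
        elif this_grid is not None and not math.isclose(grid, this_grid):
            raise ValueError("rate series have incompatible sampling grids")
        r = np.asarray(s["rate"], dtype=float)
        keep = (
            (t >= schedule.acclimation - 1e-9)
            & (t < schedule.analysis_end() - 1e-9)
            & np.isfinite(r)
        )
        for ti, ri in zip(t[keep], r[keep]):
            phase, _ = schedule.phase_of(ti)
            obs.append((phase, ri))
    if not obs:
        raise ValueError("no observations in the periodic analysis range")
    ph = np.array([o[0] for o in obs])
    val = np.array([o[1] for o in obs])
    idx = np.floor(ph / bin_width).astype(int)
    n_bins = int(math.ceil(T / bin_width))
    rows = []
    for b in range(n_bins):
        v = val[idx == b]
        if len(v) == 0:
            continue
        lo, hi = _t_ci(v)
        rows.append(
            {
                "phase_center": (b + 0.5) * bin_width,
                "mean_rate": float(np.mean(v)),
                "ci95_low": lo,
                "ci95_high": hi,
                "n_obs": len(v),
            }
        )
    first = val[ph < T / 2]
    second = val[ph >= T / 2]
    return PhaseProfile(
        period=T,
        bins=pd.DataFrame(rows),
        half_period_means=(float(np.mean(first)), float(np.mean(second))),
        half_period_ci95=(_t_ci(first), _t_ci(second)),
    )


def population_growth_rate(division: RateEstimate, death: RateEstimate) -> float:
    """Population growth rate = division rate - death rate (min^-1)."""
    if not (
        math.isclose(division.t0, death.t0, abs_tol=1e-6)
        and math.isclose(division.t1, death.t1, abs_tol=1e-6)
    ):
        logger.warning(
            "growth rate from mismatched intervals: [%g,%g] vs [%g,%g]",
            division.t0, division.t1, death.t0, death.t1,
        )
    return division.rate - death.rate


def doubling_time(rate: float) -> float:
    """Doubling time ln(2)/rate in minutes for a per-capita rate > 0."""
    if rate <= 0:
        raise ValueError("doubling time undefined for non-positive rate")
    return math.log(2.0) / rate


def period_from_frequency(freq: float) -> float:
    """Fluctuation period 1/f in minutes for a frequency > 0 (min^-1)."""
    if freq <= 0:
        raise ValueError("period undefined for non-positive frequency")
    return 1.0 / freq


def replicate_summary(values: Iterable[float], level: float = 0.95):
    """Mean and t-based CI of per-chamber rates: (mean, (lo, hi), n).

    With a single replicate the mean is returned and the CI is (nan, nan).
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("no values")
    return float(np.mean(v)), _t_ci(v, level), len(v)


def compare_conditions(
    group_a: Iterable[float],
    group_b: Iterable[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on per-chamber mean rates: (t statistic, p value).

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    classic Student test.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
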