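"""Reporter-fluorescence quantification.

Three readouts, each computed from per-cell trace tables (one row per cell
per frame with whole-cell and optionally nuclear mean fluorescence):

* **fold change** of a transcriptional reporter:
  ``FC_i(t) = (F_i(t) - Fbar(t0)) / Fbar(t0)`` where ``Fbar(t0)`` is the
  across-cell mean at a baseline frame (by default the first frame after
  the acclimation hour);
* **nuclear enrichment** of a tagged kinase:
  ``E_i(t) = nucleus_mean_i(t) / cell_mean_i(t)``, the whole-cell mean
  including nuclear pixels, so E = 1 means no enrichment;
* **relative fluorescence** of the fluorescein chip-calibration assay:
  ``RF_t = (F_t - F_min)/(F_max - F_min)`` with F_min/F_max the means over
  configured low/high time windows.

Population curves are across-cell means with t-based 95% confidence
intervals; cells absent at a time point are simply omitted (no imputation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["fov", "object_id", "time", "cell_mean_fluor"]


def _check_traces(traces: pd.DataFrame, need_nucleus: bool = False) -> pd.DataFrame:
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if need_nucleus and "nucleus_mean_fluor" not in traces.columns:
        missing.append("nucleus_mean_fluor")
    if missing:
        raise ValueError(f"trace table missing column(s): {', '.join(missing)}")
    return traces


def min_track_length_filter(traces: pd.DataFrame, min_minutes: float) -> pd.DataFrame:
    """Keep only cells tracked for at least ``min_minutes`` (span of trace)."""
    span = traces.groupby(["fov", "object_id"])["time"].agg(lambda s: s.max() - s.min())
    keep = span[span >= min_minutes].index
    return traces.set_index(["fov", "object_id"]).loc[keep].reset_index()


def fold_change(
    traces: pd.DataFrame,
    baseline_time: float | None = None,
    min_track_length: float = 0.0,
) -> pd.DataFrame:
    """Per-cell reporter fold change against the baseline population mean.

    ``baseline_time`` defaults to the earliest time present (callers that
    exclude the acclimation hour should pass the first post-acclimation
    time).  Returns the input with a ``fold_change`` column added.
    """
    traces = _check_traces(traces)
    if min_track_length > 0:
        traces = min_track_length_filter(traces, min_track_length)
    if baseline_time is None:
        baseline_time = float(traces["time"].min())
    base = traces.loc[np.isclose(traces["time"], baseline_time), "cell_mean_fluor"]
    if len(base) == 0:
        raise ValueError(f"no cells at baseline time {baseline_time}")
    fbar0 = float(base.mean())
    if fbar0 <= 0:
        raise ValueError(f"baseline population mean must be > 0, got {fbar0}")
    out = traces.copy()
    out["fold_change"] = (out["cell_mean_fluor"] - fbar0) / fbar0
    return out


def nuclear_enrichment(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-cell nuclear enrichment: nucleus mean over whole-cell mean.

    Requires ``nucleus_mean_fluor``; the whole-cell mean is taken to
    include nuclear pixels, so uniformly distributed fluorescence gives
    exactly 1.  Returns the input with an ``enrichment`` column added.
    """
    traces = _check_traces(traces, need_nucleus=True)
    if traces["nucleus_mean_fluor"].isna().any():
        raise ValueError("nucleus_mean_fluor contains missing values")
    cm = traces["cell_mean_fluor"].to_numpy(dtype=float)
    if (cm <= 0).any():
        raise ValueError("cell_mean_fluor must be positive")
    out = traces.copy()
    out["enrichment"] = traces["nucleus_mean_fluor"].to_numpy(dtype=float) / cm
    return out


@dataclass
class RelativeFluorescenceResult:
    series: pd.DataFrame  # time, value, rf, out_of_range
    f_min: float
    f_max: float


def relative_fluorescence(
    times: Sequence[float],
    values: Sequence[float],
    min_windows: Sequence[tuple[float, float]] = ((30.0, 40.0), (70.0, 80.0)),
    max_windows: Sequence[tuple[float, float]] = ((10.0, 20.0), (50.0, 60.0)),
) -> RelativeFluorescenceResult:
    """Normalize a region-mean fluorescein series to [0, 1].

    F_min / F_max are the means over the unions of the given calibration
    windows (defaults follow the 20-min on / 20-min off valve program:
    lows at 30-40 and 70-80 min, highs at 10-20 and 50-60 min).  RF is not
    clipped; values outside [0, 1] are flagged, not altered.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) != len(v) or len(t) == 0:
        raise ValueError("times and values must be equal-length and non-empty")

    def window_mean(windows):
        sel = np.zeros(len(t), dtype=bool)
        for lo, hi in windows:
            sel |= (t >= lo) & (t <= hi)
        if not sel.any():
            raise ValueError(f"no samples inside calibration windows {list(windows)}")
        return float(v[sel].mean())

    f_min = window_mean(min_windows)
    f_max = window_mean(max_windows)
    if f_max <= f_min:
        raise ValueError(f"F_max ({f_max}) must exceed F_min ({f_min})")
    rf = (v - f_min) / (f_max - f_min)
    oor = (rf < 0) | (rf > 1)
    if oor.any():
        logger.info("relative_fluorescence: %d value(s) outside [0, 1]", int(oor.sum()))
    return RelativeFluorescenceResult(
        series=pd.DataFrame({"time": t, "value": v, "rf": rf, "out_of_range": oor}),
        f_min=f_min,
        f_max=f_max,
    )


def population_curve(
    traces: pd.DataFrame,
    value_column: str,
    times: Sequence[float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Across-cell mean with t-based CI at each time point.

    Returns columns time, mean, ci95_low, ci95_high, n; single-cell time
    points get NaN CIs.
    """
    if value_column not in traces.columns:
        raise ValueError(f"no column {value_column!r} in traces")
    rows = []
    grouped = traces.groupby("time")[value_column]
    wanted = set(np.round(times, 9)) if times is not None else None
    for t, vals in grouped:
        if wanted is not None and round(float(t), 9) not in wanted:
            continue
        v = vals.to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError(f"empty time point {t}")
        m = float(v.mean())
        if len(v) >= 2:
            half = stats.t.ppf((1 + level) / 2, len(v) - 1) * v.std(ddof=1) / math.sqrt(len(v))
            lo, hi = m - half, m + half
        else:
            lo = hi = math.nan
        rows.append({"time": float(t), "mean": m, "ci95_low": lo, "ci95_high": hi, "n": len(v)})
    if times is not None:
        have = {r["time"] for r in rows}
        missing = [t for t in times if round(float(t), 9) not in {round(h, 9) for h in have}]
        if missing:
            raise ValueError(f"no cells at requested time(s) {missing[:5]}")
    return pd.DataFrame(rows).sort_values("time").reset_index(drop=True)


def fit_adaptation_half_life(
    curve: pd.DataFrame,
    baseline: float = 1.0,
    peak_time: float | None = None,
    fit_span: float | None = None,
) -> float:
    """Half-life (min) of post-peak exponential decay of a population curve.

    Fits log(mean - baseline) against time from the curve's peak onward
    (optionally limited to ``fit_span`` minutes); used to recover the
    simulated adaptation kinetics from measured enrichment curves.
    """
    t = curve["time"].to_numpy(dtype=float)
    y = curve["mean"].to_numpy(dtype=float) - baseline
    if peak_time is None:
        peak_time = float(t[int(np.argmax(y))])
    sel = t >= peak_time - 1e-9
    if fit_span is not None:
        sel &= t <= peak_time + fit_span + 1e-9
    t_fit, y_fit = t[sel], y[sel]
    pos = y_fit > 0
    if pos.sum() < 3:
        raise ValueError("not enough positive post-peak points to fit a decay")
    res = stats.linregress(t_fit[pos], np.log(y_fit[pos]))
    if res.slope >= 0:
        raise ValueError("post-peak curve does not decay")
    return math.log(2.0) / -res.slope
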