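"""Read, validate, and write per-field-of-view nucleus-tracking tables.

The segmentation/tracking stage (performed upstream, outside this package)
emits one CSV per field of view (FOV): one row per detected nucleus per
frame, with the nucleus identity, the identity of the parental nucleus when
the object appeared by division, the nucleus centroid and area, and an
optional ``dead`` flag added by manual inspection (the nucleus of a dead
cell can stay fluorescent and trackable for hours).

Tables are carried as plain :class:`pandas.DataFrame` objects with a fixed
column schema; ``time`` is explicit in minutes rather than inferred from the
frame index, so that frames dropped for focus failures leave correct
regression abscissae behind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a tracking table
COLUMNS = ["fov", "frame", "time", "object_id", "parent_id", "x", "y", "size", "dead"]
REQUIRED_COLUMNS = ["fov", "frame", "time", "object_id", "parent_id", "x", "y", "size"]


@dataclass(frozen=True)
class TrackingWindow:
    """Fixed rectangular counting window, pixels, half-open bounds [min, max).

    The default is the 1928x1928 window centered in a 2048x2048 field,
    leaving a 60-px margin on every side so boundary crossings are observable.
    """

    x_min: float = 60.0
    x_max: float = 1988.0
    y_min: float = 60.0
    y_max: float = 1988.0

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("window bounds must satisfy min < max")

    @classmethod
    def centered(cls, side: float = 1928.0, frame_side: float = 2048.0) -> "TrackingWindow":
        m = (frame_side - side) / 2
        return cls(m, m + side, m, m + side)

    def contains(self, x, y):
        """Vectorized centroid membership test (half-open)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)

    def shrunk(self, fraction: float) -> "TrackingWindow":
        """Window with each side shrunk by ``fraction``, same center."""
        dx = (self.x_max - self.x_min) * fraction / 2
        dy = (self.y_max - self.y_min) * fraction / 2
        return TrackingWindow(self.x_min + dx, self.x_max - dx, self.y_min + dy, self.y_max - dy)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "dead" not in df.columns:
        df["dead"] = False
    df["fov"] = df["fov"].astype(str)
    df["frame"] = df["frame"].astype(np.int64)
    df["time"] = df["time"].astype(float)
    df["object_id"] = df["object_id"].astype(np.int64)
    df["parent_id"] = df["parent_id"].astype("Int64")
    for c in ("x", "y", "size"):
        df[c] = df[c].astype(float)
    df["dead"] = df["dead"].astype(bool)
    return df[COLUMNS].sort_values(["fov", "frame", "object_id"], kind="stable").reset_index(drop=True)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and structural invariants; return the normalized table.

    Raises ``ValueError`` naming the offending column/records on: missing
    required columns, duplicate ``(fov, frame, object_id)``, time not
    strictly increasing with frame within a FOV, inconsistent time across
    objects of one frame, or a ``dead`` flag that reverts to alive.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = _normalize(df)
    dup = df.duplicated(subset=["fov", "frame", "object_id"])
    if dup.any():
        bad = df.loc[dup, ["fov", "frame", "object_id"]].iloc[0]
        raise ValueError(
            f"duplicate (fov, frame, object_id): ({bad.fov}, {bad.frame}, {bad.object_id})"
        )
    for fov, g in df.groupby("fov", sort=False):
        ft = g.drop_duplicates("frame")[["frame", "time"]].sort_values("frame")
        if (g.groupby("frame")["time"].nunique() > 1).any():
            raise ValueError(f"fov {fov}: inconsistent time within a frame")
        if not ft["time"].is_monotonic_increasing or ft["time"].duplicated().any():
            raise ValueError(f"fov {fov}: time must strictly increase with frame")
        died = g[g["dead"]].groupby("object_id")["frame"].min()
        if len(died):
            late = g.merge(died.rename("death_frame"), on="object_id")
            revert = late[(late["frame"] > late["death_frame"]) & (~late["dead"])]
            if len(revert):
                oid = int(revert.iloc[0]["object_id"])
                raise ValueError(f"fov {fov}: object {oid} reverts from dead to alive")
    return df


def read_tracking_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a tracking CSV.

    ``column_map`` renames foreign-dialect headers to the canonical names
    (e.g. ``{"trackId": "object_id"}``).  The ``dead`` column is optional and
    defaults to False; null ``parent_id`` is an empty cell.
    """
    df = pd.read_csv(path, dtype={"fov": str} if column_map is None else None)
    if column_map:
        df = df.rename(columns=column_map)
    df = validate_table(df)
    for fov, g in df.groupby("fov", sort=False):
        logger.info("read %s: fov %s, %d rows, %d frames", path, fov, len(g), g["frame"].nunique())
    return df


def write_tracking_table(table: pd.DataFrame, path) -> None:
    """Write a tracking table as CSV with the canonical header order.

    Null ``parent_id`` becomes an empty cell; floats keep full precision so
    write-then-read is the identity.
    """
    validate_table(table)[COLUMNS].to_csv(path, index=False)


def annotate_deaths(
    table: pd.DataFrame, death_events: Iterable[Tuple[str, int, int]]
) -> pd.DataFrame:
    """Mark cells dead from a frame onward.

    ``death_events`` holds ``(fov, object_id, frame)`` triples from manual
    inspection of bright-field images.  Each object's flag is set from the
    given frame to its last appearance; multiple annotations for one object
    resolve to the earliest frame (death is irreversible).  Idempotent.
    """
    df = _normalize(table)
    earliest: dict[tuple[str, int], int] = {}
    for fov, oid, frame in death_events:
        key = (str(fov), int(oid))
        earliest[key] = min(earliest.get(key, frame), int(frame))
    for (fov, oid), frame in earliest.items():
        sel = (df["fov"] == fov) & (df["object_id"] == oid)
        if not sel.any():
            raise ValueError(f"unknown object {oid} in fov {fov}")
        if frame < int(df.loc[sel, "frame"].min()):
            raise ValueError(
                f"death frame {frame} precedes first appearance of object {oid} in fov {fov}"
            )
        if not (sel & (df["frame"] == frame)).any():
            raise ValueError(f"object {oid} in fov {fov} not present at frame {frame}")
        df.loc[sel & (df["frame"] >= frame), "dead"] = True
    return df


def drop_frames(table: pd.DataFrame, frames_to_exclude: Sequence[int], fov: str | None = None) -> pd.DataFrame:
    """Remove whole frames (out-of-focus exclusion); timestamps untouched.

    Frames not present are ignored with a log line.  Applies to one FOV if
    given, else to all.
    """
    df = _normalize(table)
    frames = set(int(f) for f in frames_to_exclude)
    present = set(df["frame"].unique() if fov is None else df.loc[df["fov"] == fov, "frame"].unique())
    ignored = frames - present
    if ignored:
        logger.info("drop_frames: %d frame(s) not present, ignored: %s", len(ignored), sorted(ignored))
    sel = df["frame"].isin(frames)
    if fov is not None:
        sel &= df["fov"] == fov
    return df.loc[~sel].reset_index(drop=True)
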