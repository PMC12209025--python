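"""Tracking-series container, tracker-export reader and per-second discretisation.

Tracking is single-point (centre of mass), expressed in the maze frame with
the origin at the maze centre.  Frames are binned into 1-s windows and each
window's set of occupied segments is recorded; an optional linear
interpolation between consecutive samples fills in segments skipped when the
animal moves more than one grid unit per frame (undersampling at high speed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CENTRE, OFF_MAZE, MazeGeometry, Segment, assign_segment

__all__ = [
    "TrackingSeries",
    "OccupancySequence",
    "read_tracking",
    "discretize",
]

logger = logging.getLogger("epmneg")

#: Movement speed above which segment resolution becomes unreliable (cm/s).
DEFAULT_SPEED_WARN = 25.0


class TrackingInputError(ValueError):
    """Raised for unusable tracking input."""


@dataclass(frozen=True)
class TrackingSeries:
    """Time-stamped centre-of-mass coordinates for one subject."""

    subject_id: str
    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size == 0:
            raise TrackingInputError("empty tracking series")
        if np.any(np.diff(t) <= 0):
            raise TrackingInputError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != t.shape or self.y.shape != t.shape:
            raise TrackingInputError("t, x, y must have equal length")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class OccupancySequence:
    """Per-second occupancy records derived from a tracking series.

    ``records[k]`` is the set of segments touched during second ``k``;
    ``centre_flags[k]`` / ``off_maze_flags[k]`` mark seconds containing
    centre-zone or off-maze samples; ``zones[k]`` is the second's dominant
    zone ('open', 'closed', 'centre' or 'off_maze').
    """

    subject_id: str
    records: list[set[Segment]]
    centre_flags: np.ndarray
    off_maze_flags: np.ndarray
    zones: list[str]
    speeds: np.ndarray  # per-sample speed, cm/s (first sample = 0)
    geometry: MazeGeometry

    @property
    def duration(self) -> int:
        return len(self.records)


_READER_PRESETS = {
    # Generic export: explicit seconds plus cartesian cm.
    "generic": {"time": "time_s", "x": "x_cm", "y": "y_cm"},
    # Wide per-frame export (frame index, x, y) as produced by video trackers.
    "frames": {"time": "frame", "x": "x", "y": "y"},
}


def read_tracking(
    path,
    subject_id: str | None = None,
    columns: dict[str, str] | None = None,
    preset: str = "generic",
    frame_rate: float | None = None,
    unit_scale: float = 1.0,
    sep: str = ",",
) -> TrackingSeries:
    """Read a delimited tracker export into a :class:`TrackingSeries`.

    ``columns`` maps the roles 'time', 'x', 'y' to column names, overriding
    the ``preset``.  When ``frame_rate`` is given the time column is treated
    as a frame index and converted to seconds.  ``unit_scale`` converts the
    coordinate unit to cm (e.g. 0.1 for mm).
    """
    cols = dict(_READER_PRESETS[preset])
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise TrackingInputError(
            f"tracking file {path} is missing columns: {', '.join(missing)}"
        )
    t = df[cols["time"]].to_numpy(dtype=float)
    if frame_rate is not None:
        t = t / float(frame_rate)
    return TrackingSeries(
        subject_id=subject_id or str(path),
        t=t,
        x=df[cols["x"]].to_numpy(dtype=float) * unit_scale,
        y=df[cols["y"]].to_numpy(dtype=float) * unit_scale,
        frame_rate=frame_rate,
    )


def _interpolated_points(x0, y0, x1, y1, step: float):
    """Points strictly between two samples, spaced at most ``step`` apart."""
    dist = float(np.hypot(x1 - x0, y1 - y0))
    n = int(np.ceil(dist / step))
    if n <= 1:
        return ()
    frac = np.arange(1, n) / n
    return zip(x0 + frac * (x1 - x0), y0 + frac * (y1 - y0))


def discretize(
    track: TrackingSeries,
    geometry: MazeGeometry,
    interpolate: bool = True,
    speed_warn: float = DEFAULT_SPEED_WARN,
) -> OccupancySequence:
    """Bin a tracking series into per-second segment-occupancy records.

    A segment counts as occupied in second ``k`` when any frame (or, with
    ``interpolate``, any point on the straight line between consecutive
    frames whose displacement exceeds one grid unit) inside ``[k, k + 1)``
    touches it.  Per-sample speeds are computed and samples faster than
    ``speed_warn`` cm/s are reported through the package logger, since such
    speeds undersample the grid.
    """
    t = track.t - track.t[0]  # clock starts at the first sample
    n_seconds = int(np.floor(t[-1])) + 1
    records: list[set[Segment]] = [set() for _ in range(n_seconds)]
    zone_counts: list[dict[str, int]] = [
        {"open": 0, "closed": 0, "centre": 0, "off_maze": 0} for _ in range(n_seconds)
    ]
    centre_flags = np.zeros(n_seconds, dtype=bool)
    off_flags = np.zeros(n_seconds, dtype=bool)

    dt = np.diff(t)
    dist = np.hypot(np.diff(track.x), np.diff(track.y))
    speeds = np.concatenate([[0.0], dist / dt])
    n_fast = int(np.sum(speeds > speed_warn))
    if n_fast:
        logger.warning(
            "subject %s: %d samples exceed %.0f cm/s; grid resolution may be "
            "insufficient at this frame rate",
            track.subject_id,
            n_fast,
            speed_warn,
        )

    def add_point(sec: int, px: float, py: float) -> None:
        where = assign_segment((px, py), geometry)
        if where is CENTRE:
            centre_flags[sec] = True
            zone_counts[sec]["centre"] += 1
        elif where is OFF_MAZE:
            off_flags[sec] = True
            zone_counts[sec]["off_maze"] += 1
        else:
            records[sec].add(where)
            zone_counts[sec][where.arm_type.value] += 1

    for i in range(t.size):
        sec = min(int(np.floor(t[i])), n_seconds - 1)
        add_point(sec, track.x[i], track.y[i])
        if interpolate and i + 1 < t.size and dist[i] > geometry.grid_resolution:
            for px, py in _interpolated_points(
                track.x[i], track.y[i], track.x[i + 1], track.y[i + 1],
                geometry.grid_resolution / 2.0,
            ):
                add_point(sec, px, py)

    zones: list[str] = []
    prev = "centre"
    for counts in zone_counts:
        best = max(counts.values())
        if best == 0:
            zones.append(prev)
            continue
        leaders = [z for z, c in counts.items() if c == best]
        # Ties resolve toward the previous second's zone.
        zone = prev if prev in leaders else leaders[0]
        zones.append(zone)
        prev = zone

    return OccupancySequence(
        subject_id=track.subject_id,
        records=records,
        centre_flags=centre_flags,
        off_maze_flags=off_flags,
        zones=zones,
        speeds=speeds,
        geometry=geometry,
    )
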