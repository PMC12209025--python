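"""Novel exploration growth (NEG) and conventional open-arm measures.

NEG is the cumulative percentage of a scope's grid segments (open arms,
closed arms, or the whole maze excluding the centre) that have received
their *first* visit by each second of the test.  First visits index naive
exploration; revisits index informed preferencing and do not change NEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ArmType, MazeGeometry
from .tracking import OccupancySequence

__all__ = [
    "NEGSeries",
    "ConventionalMeasures",
    "compute_neg",
    "compute_conventional",
    "neg_to_frame",
    "write_neg",
    "read_neg",
]

SCOPES = ("total", "open", "closed")


@dataclass(frozen=True)
class NEGSeries:
    """Cumulative percent of a scope first-visited by each second."""

    subject_id: str
    scope: str
    times: np.ndarray  # seconds
    neg: np.ndarray  # percent, non-decreasing in [0, 100]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "neg", np.asarray(self.neg, dtype=float))
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.times.shape != self.neg.shape:
            raise ValueError("times and neg must have equal length")

    def at(self, time: float) -> float:
        """NEG at ``time`` (step interpolation, last value carried forward)."""
        idx = int(np.searchsorted(self.times, time, side="right")) - 1
        return float(self.neg[max(idx, 0)])


@dataclass(frozen=True)
class ConventionalMeasures:
    """Latency to first open-arm entry, open entries, and open-arm time."""

    subject_id: str
    latency_open: float  # s; equals test duration when never entered
    entries_open: int
    time_open: float  # s
    duration: float


def compute_neg(
    occ: OccupancySequence, geometry: MazeGeometry, scope: str = "total"
) -> NEGSeries:
    """Aggregate first visits into a cumulative percent-explored series.

    Centre-zone and off-maze samples contribute nothing; the centre holds no
    segments by construction.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    n_scope = geometry.n_segments(scope)
    keep = {
        "total": (ArmType.OPEN, ArmType.CLOSED),
        "open": (ArmType.OPEN,),
        "closed": (ArmType.CLOSED,),
    }[scope]
    visited: set = set()
    counts = np.empty(occ.duration, dtype=float)
    for k, segs in enumerate(occ.records):
        visited.update(s for s in segs if s.arm_type in keep)
        counts[k] = len(visited)
    return NEGSeries(
        subject_id=occ.subject_id,
        scope=scope,
        times=np.arange(occ.duration, dtype=float),
        neg=100.0 * counts / n_scope,
    )


def compute_conventional(
    occ: OccupancySequence, geometry: MazeGeometry
) -> ConventionalMeasures:
    """Latency, entry count and open-arm time from an occupancy sequence.

    The latency is the first second containing any open-arm segment (the test
    duration if none).  An entry is a transition of the second-level dominant
    zone from non-open to open; open-arm time counts seconds whose dominant
    zone is open.
    """
    duration = occ.duration
    latency = float(duration)
    for k, segs in enumerate(occ.records):
        if any(s.arm_type is ArmType.OPEN for s in segs):
            latency = float(k)
            break
    entries = 0
    prev_open = False
    time_open = 0
    for zone in occ.zones:
        is_open = zone == "open"
        if is_open and not prev_open:
            entries += 1
        if is_open:
            time_open += 1
        prev_open = is_open
    if entries == 0:
        latency, time_open = float(duration), 0
    return ConventionalMeasures(
        subject_id=occ.subject_id,
        latency_open=latency,
        entries_open=entries,
        time_open=float(time_open),
        duration=float(duration),
    )


def neg_to_frame(series: list[NEGSeries]) -> pd.DataFrame:
    """Stack NEG series into tidy long format."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "scope": s.scope,
                "time_s": s.times,
                "neg_pct": s.neg,
            }
        )
        for s in series
    ]
    return pd.concat(frames, ignore_index=True)


def write_neg(series: list[NEGSeries], path, sep: str = ",") -> None:
    neg_to_frame(series).to_csv(path, sep=sep, index=False)


def read_neg(path, sep: str = ",") -> list[NEGSeries]:
    df = pd.read_csv(path, sep=sep)
    out = []
    for (subject, scope), grp in df.groupby(["subject_id", "scope"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            NEGSeries(
                subject_id=str(subject),
                scope=str(scope),
                times=grp["time_s"].to_numpy(),
                neg=grp["neg_pct"].to_numpy(),
            )
        )
    return out
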