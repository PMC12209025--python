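"""Elevated plus maze geometry and the unidimensional segment grid.

The maze is modelled as four arms radiating from a central square, with the
origin of the coordinate frame at the maze centre.  Each arm is divided along
its length into segments of ``grid_resolution`` cm that span the full arm
width; the centre square contains no segments and is excluded from every
exploration calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

__all__ = [
    "ArmType",
    "Segment",
    "CENTRE",
    "OFF_MAZE",
    "MazeGeometry",
    "build_geometry",
    "assign_segment",
]


class ArmType(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


class Segment(NamedTuple):
    """A single grid cell: (arm type, arm index in {1, 2}, depth from centre).

    ``depth`` counts outward from the centre boundary, starting at 1.
    """

    arm_type: ArmType
    arm_index: int
    depth: int


class _Zone(str, Enum):
    CENTRE = "centre"
    OFF_MAZE = "off_maze"


CENTRE = _Zone.CENTRE
OFF_MAZE = _Zone.OFF_MAZE


class GeometryError(ValueError):
    """Raised for inconsistent maze dimensions."""


@dataclass(frozen=True)
class MazeGeometry:
    """Maze dimensions and the derived segment index space.

    Parameters
    ----------
    arm_length : float
        Length of each arm in cm (centre boundary to tip).
    arm_width : float
        Arm width in cm.
    centre_size : float
        Side of the central square in cm.
    grid_resolution : float
        Along-arm segment depth in cm; must divide ``arm_length``.
    open_axis : str
        Axis ("x" or "y") along which the open arms lie; the closed arms lie
        along the orthogonal axis.
    """

    arm_length: float = 50.0
    arm_width: float = 10.0
    centre_size: float = 10.0
    grid_resolution: float = 1.0
    open_axis: str = "x"

    def __post_init__(self) -> None:
        if self.arm_length <= 0 or self.arm_width <= 0 or self.centre_size <= 0:
            raise GeometryError("maze dimensions must be positive")
        if self.grid_resolution <= 0:
            raise GeometryError("grid_resolution must be positive")
        n = self.arm_length / self.grid_resolution
        if abs(n - round(n)) > 1e-9:
            raise GeometryError(
                f"grid_resolution {self.grid_resolution} does not divide "
                f"arm_length {self.arm_length}"
            )
        if self.open_axis not in ("x", "y"):
            raise GeometryError("open_axis must be 'x' or 'y'")

    @property
    def segments_per_arm(self) -> int:
        return round(self.arm_length / self.grid_resolution)

    def n_segments(self, scope: str = "total") -> int:
        """Number of segments in a scope ('open', 'closed' or 'total')."""
        per_type = 2 * self.segments_per_arm
        if scope == "total":
            return 2 * per_type
        if scope in ("open", "closed"):
            return per_type
        raise ValueError(f"unknown scope {scope!r}")

    def segments(self, scope: str = "total"):
        """Iterate over all segment identifiers of a scope."""
        types = {
            "total": (ArmType.OPEN, ArmType.CLOSED),
            "open": (ArmType.OPEN,),
            "closed": (ArmType.CLOSED,),
        }[scope]
        for arm_type in types:
            for arm_index in (1, 2):
                for depth in range(1, self.segments_per_arm + 1):
                    yield Segment(arm_type, arm_index, depth)

    def segment_centre(self, seg: Segment) -> tuple[float, float]:
        """Cartesian coordinates (cm) of a segment's midpoint."""
        half = self.centre_size / 2.0
        along = half + (seg.depth - 0.5) * self.grid_resolution
        sign = 1.0 if seg.arm_index == 1 else -1.0
        on_open_axis = seg.arm_type is ArmType.OPEN
        axis_is_x = (self.open_axis == "x") == on_open_axis
        return (sign * along, 0.0) if axis_is_x else (0.0, sign * along)


def build_geometry(
    arm_length: float = 50.0,
    arm_width: float = 10.0,
    centre_size: float = 10.0,
    grid_resolution: float = 1.0,
    open_axis: str = "x",
) -> MazeGeometry:
    """Construct a validated :class:`MazeGeometry`."""
    return MazeGeometry(arm_length, arm_width, centre_size, grid_resolution, open_axis)


def assign_segment(point: tuple[float, float], geometry: MazeGeometry):
    """Map a tracked point to a segment identifier, CENTRE or OFF_MAZE.

    Depth intervals are half-open [d, d + resolution) counted from the centre
    boundary, with the final interval closed at the arm tip so that the
    mapping is total on the maze surface.
    """
    x, y = point
    half = geometry.centre_size / 2.0
    half_w = geometry.arm_width / 2.0
    if abs(x) <= half and abs(y) <= half:
        return CENTRE
    # Candidate arm along x, then along y.
    for axis, along, across in (("x", x, y), ("y", y, x)):
        if abs(across) <= half_w and half < abs(along) <= half + geometry.arm_length:
            arm_type = ArmType.OPEN if geometry.open_axis == axis else ArmType.CLOSED
            arm_index = 1 if along > 0 else 2
            depth_cm = abs(along) - half
            depth = int(depth_cm // geometry.grid_resolution) + 1
            depth = min(depth, geometry.segments_per_arm)  # close the tip interval
            return Segment(arm_type, arm_index, depth)
    return OFF_MAZE
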