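"""Constant-speed trajectory synthesis from target NEG curves.

The generator turns per-arm-type NEG curves into a coordinate path obeying
the simulation heuristics: movement speed is constant and identical across
arm types, and the first entry into an arm is followed by full exploration
of that arm and an immediate exit back to the centre.  Entry times are read
off the target curves (the time each arm's first segment is due), so a
phenotype's curve shape fixes the order and timing of arm visits.

A constant-speed walker cannot track an arbitrary smooth sigmoid exactly —
each arm is swept as a linear ramp and crossing between arms costs transit
time — so the realized curve is checked against the target after an internal
round trip through discretisation; ``strict`` mode raises when the deviation
exceeds the tolerance.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import ArmType, MazeGeometry
from .neg import NEGSeries, compute_neg
from .simulate import PhenotypeParams, sigmoid_curve
from .tracking import TrackingSeries, discretize

__all__ = ["GenerationError", "simulate_trajectory", "phenotype_trajectory"]

logger = logging.getLogger("epmneg")


class GenerationError(RuntimeError):
    """Raised when no feasible path reproduces the target curves."""


def _arm_point(geometry: MazeGeometry, arm_type: ArmType, arm_index: int, along: float):
    """Cartesian point at distance ``along`` from the origin on an arm axis."""
    sign = 1.0 if arm_index == 1 else -1.0
    axis_is_x = (geometry.open_axis == "x") == (arm_type is ArmType.OPEN)
    return (sign * along, 0.0) if axis_is_x else (0.0, sign * along)


def simulate_trajectory(
    curves: dict[str, NEGSeries],
    geometry: MazeGeometry,
    speed: float = 5.0,
    seed: int | None = None,
    frame_rate: float = 25.0,
    tol_segments: float = 2.0,
    strict: bool = False,
    subject_id: str | None = None,
) -> TrackingSeries:
    """Generate a coordinate path whose discretisation follows ``curves``.

    ``curves`` maps arm-type scope ('open'/'closed') to the target NEG
    series for that scope.  The walker starts at the maze centre, enters
    each arm when its first segment is due, sweeps it to the tip at
    ``speed`` cm/s, exits immediately and waits at the centre until the
    next arm is due.  ``seed`` adds no randomness at present and is kept
    for interface stability.

    Raises :class:`GenerationError` in ``strict`` mode when the realized
    NEG deviates from a target curve by more than ``tol_segments`` grid
    segments at any second; otherwise the deviation is logged.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    half = geometry.centre_size / 2.0
    arm_reach = half + geometry.arm_length
    per_arm = geometry.segments_per_arm

    duration = max(float(s.times[-1]) for s in curves.values())

    # Entry deadline per physical arm: first second its first segment is due.
    events: list[tuple[float, str, int]] = []
    for scope, series in curves.items():
        counts = series.neg * geometry.n_segments(scope) / 100.0
        for arm_index in (1, 2):
            need = (arm_index - 1) * per_arm + 1
            due = np.nonzero(counts >= need - 1e-6)[0]
            if due.size:
                events.append((float(series.times[due[0]]), scope, arm_index))
    events.sort()

    waypoints: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    t_cur = 0.0
    for deadline, scope, arm_index in events:
        arm_type = ArmType(scope)
        depart = max(deadline - half / speed, t_cur)
        if depart > t_cur:
            waypoints.append((depart, 0.0, 0.0))  # wait at centre
        tip = _arm_point(geometry, arm_type, arm_index, arm_reach)
        t_tip = depart + arm_reach / speed
        t_back = t_tip + arm_reach / speed
        waypoints.append((t_tip, *tip))
        waypoints.append((t_back, 0.0, 0.0))
        t_cur = t_back
    if t_cur < duration:
        waypoints.append((duration, 0.0, 0.0))
    if waypoints[-1][0] > duration:
        logger.warning(
            "trajectory itinerary overruns the test duration by %.1f s",
            waypoints[-1][0] - duration,
        )

    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1] for w in waypoints])
    wy = np.array([w[2] for w in waypoints])
    frames = np.arange(0.0, max(duration, wt[-1]) + 1e-9, 1.0 / frame_rate)
    frames = frames[frames <= duration]
    track = TrackingSeries(
        subject_id=subject_id or "synthetic",
        t=frames,
        x=np.interp(frames, wt, wx),
        y=np.interp(frames, wt, wy),
        frame_rate=frame_rate,
    )

    occ = discretize(track, geometry, interpolate=True)
    worst = 0.0
    for scope, series in curves.items():
        realized = compute_neg(occ, geometry, scope)
        n = min(realized.neg.size, series.neg.size)
        r, tgt = realized.neg[:n], series.neg[:n]
        # Per-second binning credits a whole second's sweep to its starting
        # second, so the realized curve may lead the target by one second.
        lead = r - np.concatenate([tgt[1:], tgt[-1:]])
        lag = tgt - r
        dev_seg = np.max(np.maximum(np.maximum(lead, lag), 0.0)) * (
            geometry.n_segments(scope) / 100.0
        )
        worst = max(worst, float(dev_seg))
    if worst > tol_segments:
        msg = (
            f"realized NEG deviates from the target by up to {worst:.1f} "
            f"segments (tolerance {tol_segments}); the target curve is not "
            f"feasible at {speed} cm/s"
        )
        if strict:
            raise GenerationError(msg)
        logger.info(msg)
    return track


def phenotype_trajectory(
    params: PhenotypeParams,
    geometry: MazeGeometry,
    speed: float = 5.0,
    seed: int | None = None,
    frame_rate: float = 25.0,
) -> TrackingSeries:
    """Canonical heuristic trajectory for a phenotype's noise-free curves."""
    times = np.arange(int(params.duration) + 1, dtype=float)
    curves = {
        "open": NEGSeries(params.phenotype, "open", times,
                          sigmoid_curve(times, params.open_arm)),
        "closed": NEGSeries(params.phenotype, "closed", times,
                            sigmoid_curve(times, params.closed_arm)),
    }
    return simulate_trajectory(
        curves, geometry, speed=speed, seed=seed, frame_rate=frame_rate,
        subject_id=params.phenotype,
    )
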