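"""Per-observation movement-path metrics.

From the ordered fixes of a focal observation we derive the standard path
segmentation quantities: step length (straight-line distance between
consecutive 1-min locations), path length (sum of step lengths over the
observation), net displacement (first fix to last fix), straightness index
(net displacement / path length, in [0, 1]), and turn angles (change of
heading between consecutive movement steps).  Intervals without movement
are excluded from the step-length and turn-angle series but retained in
the denominator of the proportion of intervals with movement and
contribute zero to path length.

Whole-path metrics (path length, net displacement, straightness) are only
defined for complete observations (31 fixes); shorter follows still
contribute step lengths and turn angles to pooled analyses.

Turn angles are reported both signed, in (-180, 180] degrees measured
counterclockwise, and folded (absolute), in [0, 180].  By default the
heading is carried across pauses: the turn after a stationary interval
compares the new step's heading with the heading of the last moving step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import Observation

__all__ = [
    "Step",
    "PathSummary",
    "EmptyPathError",
    "compute_steps",
    "path_length",
    "net_displacement",
    "straightness_index",
    "turn_angles",
    "proportion_moving",
    "visibility_index",
    "summarize_observation",
]


class EmptyPathError(ValueError):
    """Raised when fewer than two fixes are available."""


@dataclass
class Step:
    """Displacement between two consecutive fixes.

    ``heading`` is in degrees counterclockwise from the +x axis, wrapped to
    (-180, 180], and is only meaningful when ``moved`` is true.
    """

    from_t: int
    to_t: int
    length: float
    heading: Optional[float]
    moved: bool


@dataclass
class PathSummary:
    observation_id: str
    step_lengths: list[float]          # moving steps only, meters
    path_length: Optional[float]       # complete observations only
    net_displacement: Optional[float]
    straightness_index: Optional[float]
    turn_angles_signed: list[float]    # degrees in (-180, 180]
    turn_angles_abs: list[float]       # degrees in [0, 180]
    proportion_moving: float
    visibility_index: Optional[float]
    n_intervals: int
    n_fixes: int
    complete: bool


def _wrap_deg(angle: float) -> float:
    """Wrap to (-180, 180]."""
    a = math.remainder(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    return a


def compute_steps(obs: Observation, move_epsilon: float = 0.0) -> list[Step]:
    """One :class:`Step` per consecutive fix pair.

    A step counts as movement when its Euclidean length exceeds
    ``move_epsilon`` (default 0: any recorded displacement is movement,
    since field step lengths as small as 1 cm are real).
    """
    if len(obs.fixes) < 2:
        raise EmptyPathError(
            f"{obs.observation_id}: need at least 2 fixes to form a step"
        )
    if move_epsilon < 0:
        raise ValueError("move_epsilon must be >= 0")
    steps: list[Step] = []
    for a, b in zip(obs.fixes[:-1], obs.fixes[1:]):
        dx, dy = b.x - a.x, b.y - a.y
        length = math.hypot(dx, dy)
        moved = length > move_epsilon
        heading = math.degrees(math.atan2(dy, dx)) if moved else None
        if heading is not None:
            heading = _wrap_deg(heading)
        steps.append(Step(from_t=a.t, to_t=b.t, length=length, heading=heading, moved=moved))
    return steps


def path_length(steps: list[Step]) -> float:
    """Sum of all step lengths; stationary intervals contribute zero."""
    return float(math.fsum(s.length for s in steps))


def net_displacement(obs: Observation) -> float:
    """Straight-line distance between the first and last fix."""
    if len(obs.fixes) < 2:
        raise EmptyPathError(f"{obs.observation_id}: need at least 2 fixes")
    a, b = obs.fixes[0], obs.fixes[-1]
    return math.hypot(b.x - a.x, b.y - a.y)


def straightness_index(obs: Observation, move_epsilon: float = 0.0) -> Optional[float]:
    """Net displacement divided by path length, clamped to [0, 1].

    Undefined (``None``) for a non-mover: a path of length zero has no
    shape to rate.
    """
    steps = compute_steps(obs, move_epsilon)
    total = path_length(steps)
    if total == 0.0:
        return None
    return min(1.0, max(0.0, net_displacement(obs) / total))


def turn_angles(
    steps: list[Step], carry_across_pauses: bool = True
) -> tuple[list[float], list[float]]:
    """Signed and folded turn angles between consecutive movement steps.

    Stationary intervals are not steps; with ``carry_across_pauses`` (the
    default) the heading is remembered over them, so a pause in the middle
    of a path yields one turn angle comparing the headings on either side.
    With ``carry_across_pauses=False`` any pause breaks the sequence and
    the turn spanning it is dropped.
    """
    signed: list[float] = []
    prev_heading: Optional[float] = None
    for s in steps:
        if not s.moved:
            if not carry_across_pauses:
                prev_heading = None
            continue
        if prev_heading is not None:
            signed.append(_wrap_deg(s.heading - prev_heading))
        prev_heading = s.heading
    return signed, [abs(a) for a in signed]


def proportion_moving(steps: list[Step]) -> float:
    """Fraction of 1-min intervals in which the animal moved."""
    if not steps:
        raise EmptyPathError("no steps")
    return sum(s.moved for s in steps) / len(steps)


def visibility_index(obs: Observation) -> Optional[float]:
    """Proportion of transitions whose destination was visible.

    Requires a visibility flag on every non-initial fix; if any flag is
    absent the index is undefined and ``None`` is returned with a warning.
    """
    flags = [fx.visible_from_previous for fx in obs.fixes[1:]]
    if not flags:
        return None
    if any(f is None for f in flags):
        warnings.warn(
            f"{obs.observation_id}: visibility flags incomplete; index undefined",
            stacklevel=2,
        )
        return None
    return sum(flags) / len(flags)


def summarize_observation(obs: Observation, move_epsilon: float = 0.0,
                          carry_across_pauses: bool = True) -> PathSummary:
    """All per-observation metrics in one pass.

    Whole-path metrics are reported only for complete (31-fix) follows;
    truncated observations get ``None`` there but still contribute their
    step lengths, turn angles and proportion moving.
    """
    steps = compute_steps(obs, move_epsilon)
    signed, folded = turn_angles(steps, carry_across_pauses)
    complete = obs.complete
    if complete:
        pl: Optional[float] = path_length(steps)
        nd: Optional[float] = net_displacement(obs)
        si = straightness_index(obs, move_epsilon)
    else:
        pl = nd = si = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vis = visibility_index(obs)
    return PathSummary(
        observation_id=obs.observation_id,
        step_lengths=[s.length for s in steps if s.moved],
        path_length=pl,
        net_displacement=nd,
        straightness_index=si,
        turn_angles_signed=signed,
        turn_angles_abs=folded,
        proportion_moving=proportion_moving(steps),
        visibility_index=vis,
        n_intervals=len(steps),
        n_fixes=len(obs.fixes),
        complete=complete,
    )


def summaries_frame(summaries: list[PathSummary]):
    """Flatten summaries to a pandas DataFrame (one row per observation)."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append(
            {
                "observation_id": s.observation_id,
                "n_fixes": s.n_fixes,
                "n_intervals": s.n_intervals,
                "complete": s.complete,
                "n_moving_steps": len(s.step_lengths),
                "median_step_length_m": float(np.median(s.step_lengths)) if s.step_lengths else np.nan,
                "path_length_m": np.nan if s.path_length is None else s.path_length,
                "net_displacement_m": np.nan if s.net_displacement is None else s.net_displacement,
                "straightness_index": np.nan if s.straightness_index is None else s.straightness_index,
                "median_turn_angle_abs_deg": float(np.median(s.turn_angles_abs)) if s.turn_angles_abs else np.nan,
                "proportion_moving": s.proportion_moving,
                "visibility_index": np.nan if s.visibility_index is None else s.visibility_index,
            }
        )
    return pd.DataFrame(rows)
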