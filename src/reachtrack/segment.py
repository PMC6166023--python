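"""Target-square state machine and travel/endpoint segmentation.

The trial alternates a green "go-to" square between the left and right
targets.  An *arrival* is the first frame whose centroid lies inside the
active square (closed test: the boundary counts as inside); each arrival
activates the opposite square.  A subtask begins with an initiation arrival
at the left target and ends after five further arrivals (five movements).

From the arrival sequence a trial is cut into:

* travel segments — frames strictly after the last frame inside the
  departure square, through the arrival frame at the next square;
* endpoint segments — frames from the arrival through the frame of
  horizontal direction reversal (the extreme-x frame inside the target).

All frame ranges are half-open ``[start, end)`` with 0-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .protocol import Protocol, point_in_square
from .series import CentroidSeries

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-12  # displacements smaller than this count as stationary


class TruncatedTrialError(RuntimeError):
    """Series ended before the protocol completed."""

    def __init__(self, completed: List[str]):
        self.completed = completed
        super().__init__(
            f"trial truncated: completed subtasks {completed or '[]'}")


@dataclass(frozen=True)
class TargetStatus:
    """Per-frame target-square status."""
    frame_index: int
    inside_left: bool
    inside_right: bool
    active_target: str      # 'left' | 'right' | 'rest'
    subtask_id: str         # one of the six subtask labels, or 'rest'


@dataclass(frozen=True)
class Arrival:
    frame: int
    target: str             # 'left' | 'right'
    subtask_id: str


@dataclass(frozen=True)
class Segment:
    kind: str               # 'travel' | 'endpoint'
    subtask_id: str
    segment_index: int      # movement number within the subtask, 0-based
    start: int              # half-open [start, end)
    end: int
    direction: str          # 'leftward' | 'rightward'

    def __post_init__(self) -> None:
        if self.kind not in ("travel", "endpoint"):
            raise ValueError(f"bad segment kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("segment frame range must be non-empty")

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end)


class StateMachineResult(Sequence):
    """Sequence of per-frame :class:`TargetStatus` plus the arrival events."""

    def __init__(self, statuses: List[TargetStatus],
                 arrivals: List[List[Arrival]], protocol: Protocol):
        self._statuses = statuses
        self.arrivals = arrivals          # one list per subtask, in order
        self.protocol = protocol

    def __len__(self) -> int:
        return len(self._statuses)

    def __getitem__(self, i):
        return self._statuses[i]


def run_state_machine(series: CentroidSeries, protocol: Protocol,
                      min_valid_fraction: float = 0.9) -> StateMachineResult:
    """Replay the alternating-target state machine over a centroid series."""
    if series.valid_fraction < min_valid_fraction:
        raise ValueError(
            f"only {series.valid_fraction:.1%} of frames are valid; "
            f"need >= {min_valid_fraction:.0%}")
    left_c, right_c = protocol.target_centers_px(series.camera)
    order = protocol.subtask_order
    arrivals_per_subtask = protocol.movements_per_subtask + 1  # + initiation

    statuses: List[TargetStatus] = []
    arrivals: List[List[Arrival]] = [[] for _ in order]
    k = 0                       # current subtask index
    active = "left"
    n_arr = 0                   # arrivals recorded in current subtask

    for i in range(len(series)):
        if k >= len(order):
            statuses.append(TargetStatus(i, False, False, "rest", "rest"))
            continue
        sub = order[k]
        side = float(protocol.side_for(sub))
        if series.valid[i]:
            xi, yi = series.x[i], series.y[i]
            ins_l = point_in_square(xi, yi, left_c, side)
            ins_r = point_in_square(xi, yi, right_c, side)
        else:
            ins_l = ins_r = False
        in_subtask = n_arr > 0
        arrived = (ins_l if active == "left" else ins_r)
        label = sub if (in_subtask or arrived) else "rest"
        statuses.append(TargetStatus(i, ins_l, ins_r, active, label))
        if arrived:
            arrivals[k].append(Arrival(frame=i, target=active, subtask_id=sub))
            n_arr += 1
            active = "right" if active == "left" else "left"
            if n_arr == arrivals_per_subtask:
                k += 1
                n_arr = 0
                active = "left"

    if k < len(order):
        raise TruncatedTrialError(list(order[:k]))
    return StateMachineResult(statuses, arrivals, protocol)


def _find_reversal(series: CentroidSeries, arrival: int, direction: int,
                   center: Tuple[float, float], side: float) -> Optional[int]:
    """Extreme-x frame inside the target square, or None if the centroid
    exits (or the series ends) without reversing."""
    i = arrival
    n = len(series)
    while i + 1 < n:
        if not (series.valid[i + 1]
                and point_in_square(series.x[i + 1], series.y[i + 1],
                                    center, side)):
            # left the square (or dropout) still travelling forward
            return None
        d = (series.x[i + 1] - series.x[i]) * direction
        if d < -_ZERO_TOL:
            # reversal between i and i+1: extreme-x frame of the run so far
            span = slice(arrival, i + 1)
            rel = np.argmax(direction * series.x[span])
            return arrival + int(rel)
        i += 1
    return None


def extract_segments(statuses: StateMachineResult, series: CentroidSeries
                     ) -> List[Segment]:
    """Cut the series into travel and endpoint segments.

    One travel segment per movement (five per subtask); one endpoint
    segment per movement arrival, unless the centroid passes straight
    through the target without reversing, in which case that endpoint is
    missing (logged, excluded from offset averages).
    """
    protocol = statuses.protocol
    left_c, right_c = protocol.target_centers_px(series.camera)
    centers = {"left": left_c, "right": right_c}
    segments: List[Segment] = []
    for sub_arrivals in statuses.arrivals:
        for j in range(1, len(sub_arrivals)):
            prev, cur = sub_arrivals[j - 1], sub_arrivals[j]
            dep_center = centers[prev.target]
            arr_center = centers[cur.target]
            side = float(protocol.side_for(cur.subtask_id))
            direction = "rightward" if cur.target == "right" else "leftward"
            dsign = 1 if direction == "rightward" else -1
            # last frame still inside the departure square before arrival
            last_inside = prev.frame
            for i in range(prev.frame, cur.frame):
                if series.valid[i] and point_in_square(
                        series.x[i], series.y[i], dep_center, side):
                    last_inside = i
            segments.append(Segment(
                kind="travel", subtask_id=cur.subtask_id, segment_index=j - 1,
                start=last_inside + 1, end=cur.frame + 1, direction=direction))
            rev = _find_reversal(series, cur.frame, dsign, arr_center, side)
            if rev is None:
                logger.warning(
                    "no direction reversal inside target for %s movement %d; "
                    "endpoint marked missing", cur.subtask_id, j)
                continue
            segments.append(Segment(
                kind="endpoint", subtask_id=cur.subtask_id,
                segment_index=j - 1, start=cur.frame, end=rev + 1,
                direction=direction))
    return segments
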