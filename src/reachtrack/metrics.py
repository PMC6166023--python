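"""The five kinematic metrics, per segment and aggregated per subtask.

* mean speed (mm/s) — frame-pair Euclidean displacement rate over a travel
  segment;
* mean acceleration (mm/s^2) — mean absolute frame-to-frame change of
  instantaneous speed over a travel segment (each sample spans 4 raw
  frames: two consecutive two-frame speeds);
* percent speed error — signed deviation of mean speed from the trained
  25.7 mm/s;
* center offset (mm) — signed distance, projected on the travel direction,
  from the target centre to the farthest point of the endpoint segment
  (positive = overreach);
* intertarget path accuracy (IPA, %) — share of travel-segment frames
  whose centroid lies inside the direct corridor joining the two targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .protocol import Protocol
from .segment import Segment
from .series import CentroidSeries

logger = logging.getLogger(__name__)

#: column order of the metric table
METRIC_COLUMNS = ("participant_id", "age", "trial", "subtask",
                  "speed_mmps", "accel_mmps2", "speed_error_pct",
                  "center_offset_mm", "ipa_pct")
METRIC_NAMES = ("speed_mmps", "accel_mmps2", "speed_error_pct",
                "center_offset_mm", "ipa_pct")


def instantaneous_speeds(series: CentroidSeries) -> np.ndarray:
    """Speed (mm/s) between consecutive frames; NaN where either frame is
    invalid.  Element *i* is the speed between frames *i* and *i+1*."""
    mpp = series.camera.mm_per_px
    d = np.hypot(np.diff(series.x), np.diff(series.y))
    v = d * mpp * series.camera.fps
    ok = series.valid[:-1] & series.valid[1:]
    return np.where(ok, v, np.nan)


def instantaneous_speed(series: CentroidSeries, i: int) -> float:
    """Speed between frames ``i`` and ``i+1`` (mm/s), NaN if undefined."""
    return float(instantaneous_speeds(series)[i])


def segment_mean_speed(segment: Segment, series: CentroidSeries) -> float:
    """Arithmetic mean of the defined instantaneous speeds over a travel
    segment's frame pairs."""
    if segment.kind != "travel":
        raise ValueError("segment_mean_speed is defined for travel segments")
    v = instantaneous_speeds(series)[segment.start:segment.end - 1]
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return float("nan")
    return float(np.mean(v))


def segment_mean_acceleration(segment: Segment, series: CentroidSeries
                              ) -> float:
    """Mean |acceleration| (mm/s^2) over a travel segment.

    Instantaneous acceleration at pair *i* is
    ``(v_{i+1} - v_i) * fps`` with v the two-frame instantaneous speeds,
    so each sample draws on four raw frames.  Undefined (NaN, logged) for
    segments shorter than 4 frames.
    """
    if segment.kind != "travel":
        raise ValueError(
            "segment_mean_acceleration is defined for travel segments")
    if segment.n_frames < 4:
        logger.warning("segment %s/%d too short for acceleration (%d frames)",
                       segment.subtask_id, segment.segment_index,
                       segment.n_frames)
        return float("nan")
    v = instantaneous_speeds(series)[segment.start:segment.end - 1]
    a = np.diff(v) * series.camera.fps
    a = a[~np.isnan(a)]
    if len(a) == 0:
        return float("nan")
    return float(np.mean(np.abs(a)))


def percent_speed_error(mean_speed: float,
                        training_speed: float = 25.7) -> float:
    """Signed percent deviation of ``mean_speed`` from the trained speed."""
    if training_speed <= 0:
        raise ValueError("training_speed must be positive")
    return 100.0 * (mean_speed - training_speed) / training_speed


def center_offset(endpoint: Segment, series: CentroidSeries,
                  protocol: Protocol) -> float:
    """Signed horizontal offset (mm) of the farthest point reached in an
    endpoint segment from the target centre, projected on the travel
    direction: positive = past the centre (overreach)."""
    if endpoint.kind != "endpoint":
        raise ValueError("center_offset is defined for endpoint segments")
    (lx, _), (rx, _) = protocol.target_centers_px(series.camera)
    dsign = 1.0 if endpoint.direction == "rightward" else -1.0
    cx = rx if endpoint.direction == "rightward" else lx
    x = series.x[endpoint.start:endpoint.end]
    ok = series.valid[endpoint.start:endpoint.end]
    if not ok.any():
        return float("nan")
    farthest = np.max(dsign * x[ok])
    return float((farthest - dsign * cx) * series.camera.mm_per_px)


def intertarget_path_accuracy(frames: Sequence[int], series: CentroidSeries,
                              subtask_id: str, protocol: Protocol) -> float:
    """Percent of the given frames inside the inter-target corridor.

    ``frames`` are the pooled travel-segment frames of one subtask; the
    corridor boundary counts as inside.  NaN (logged) if no valid frame.
    """
    frames = np.asarray(frames, dtype=int)
    x_lo, x_hi, y_lo, y_hi = protocol.roi_bounds(subtask_id, series.camera)
    ok = series.valid[frames]
    if not ok.any():
        logger.warning("no valid frames for IPA in %s", subtask_id)
        return float("nan")
    x = series.x[frames[ok]]
    y = series.y[frames[ok]]
    inside = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    return float(100.0 * inside.sum() / ok.sum())


@dataclass(frozen=True)
class KinematicRecord:
    participant_id: str
    age: float
    trial: int
    subtask_id: str
    mean_speed: float
    mean_accel: float
    pct_speed_error: float
    center_offset: float
    ipa: float
    missing: bool = False


def summarize_trial(series: CentroidSeries, segments: List[Segment],
                    protocol: Protocol, participant_id: str = "",
                    trial: int = 1, age: float = float("nan")
                    ) -> List[KinematicRecord]:
    """Aggregate segment metrics to one record per subtask.

    Speed, acceleration and speed error average the subtask's travel
    segments; centre offset averages the available endpoint segments; IPA
    pools all travel frames of the subtask.
    """
    records = []
    for sub in protocol.subtask_order:
        travels = [s for s in segments
                   if s.subtask_id == sub and s.kind == "travel"]
        endpoints = [s for s in segments
                     if s.subtask_id == sub and s.kind == "endpoint"]
        if not travels:
            logger.warning("subtask %s has no usable travel segments", sub)
            records.append(KinematicRecord(
                participant_id, age, trial, sub, *(float("nan"),) * 5,
                missing=True))
            continue
        speeds = [segment_mean_speed(s, series) for s in travels]
        accels = [segment_mean_acceleration(s, series) for s in travels]
        errors = [percent_speed_error(v, protocol.training_speed_mm_s)
                  for v in speeds]
        offsets = [center_offset(s, series, protocol) for s in endpoints]
        offsets = [o for o in offsets if not np.isnan(o)]
        frames = np.concatenate([s.frames for s in travels])
        records.append(KinematicRecord(
            participant_id=participant_id, age=age, trial=trial,
            subtask_id=sub,
            mean_speed=float(np.nanmean(speeds)),
            mean_accel=float(np.nanmean(accels)),
            pct_speed_error=float(np.nanmean(errors)),
            center_offset=float(np.mean(offsets)) if offsets else float("nan"),
            ipa=intertarget_path_accuracy(frames, series, sub, protocol)))
    return records


def records_to_table(records: List[KinematicRecord]) -> pd.DataFrame:
    """Metric table with the canonical column order."""
    df = pd.DataFrame([{
        "participant_id": r.participant_id, "age": r.age, "trial": r.trial,
        "subtask": r.subtask_id, "speed_mmps": r.mean_speed,
        "accel_mmps2": r.mean_accel, "speed_error_pct": r.pct_speed_error,
        "center_offset_mm": r.center_offset, "ipa_pct": r.ipa,
    } for r in records])
    return df[list(METRIC_COLUMNS)]
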