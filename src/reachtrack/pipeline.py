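"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import pandas as pd

from .camera import CameraModel
from .metrics import KinematicRecord, records_to_table, summarize_trial
from .protocol import Protocol
from .segment import StateMachineResult, extract_segments, run_state_machine
from .series import CentroidSeries
from .synth import Cohort, simulate_subject_trials

logger = logging.getLogger(__name__)


def trial_metrics(series: CentroidSeries, protocol: Optional[Protocol] = None,
                  participant_id: str = "", trial: int = 1,
                  age: float = float("nan")
                  ) -> Tuple[List[KinematicRecord], StateMachineResult]:
    """Run state machine, segmentation, and metric summary on one series."""
    protocol = protocol or Protocol()
    statuses = run_state_machine(series, protocol)
    segments = extract_segments(statuses, series)
    records = summarize_trial(series, segments, protocol,
                              participant_id=participant_id, trial=trial,
                              age=age)
    return records, statuses


def cohort_metric_table(cohort: Cohort, protocol: Optional[Protocol] = None,
                        camera: Optional[CameraModel] = None) -> pd.DataFrame:
    """Simulate every trial of a cohort and run the full analysis pipeline.

    Returns the metric table: one row per participant x trial x subtask.
    """
    protocol = protocol or Protocol()
    camera = camera or CameraModel()
    records: List[KinematicRecord] = []
    for subj in cohort.subjects:
        sims = simulate_subject_trials(subj, protocol, camera)
        for t, sim in enumerate(sims, start=1):
            recs, _ = trial_metrics(sim.series, protocol,
                                    participant_id=subj.participant_id,
                                    trial=t, age=subj.age)
            records.extend(recs)
    return records_to_table(records)


def cohort_truth_table(cohort: Cohort, protocol: Optional[Protocol] = None,
                       camera: Optional[CameraModel] = None) -> pd.DataFrame:
    """Ground-truth per-subtask table straight from the generator
    (no segmentation or detection involved)."""
    import numpy as np

    protocol = protocol or Protocol()
    camera = camera or CameraModel()
    rows = []
    for subj in cohort.subjects:
        for t, sim in enumerate(simulate_subject_trials(subj, protocol,
                                                        camera), start=1):
            for sub in protocol.subtask_order:
                idx = [i for i, s in enumerate(sim.travel_segments)
                       if s.subtask_id == sub]
                eidx = [i for i, s in enumerate(sim.endpoint_segments)
                        if s.subtask_id == sub]
                rows.append({
                    "participant_id": subj.participant_id, "age": subj.age,
                    "trial": t, "subtask": sub,
                    "true_speed_mmps": float(np.mean(
                        [sim.travel_mean_speed_mm_s[i] for i in idx])),
                    "true_offset_mm": float(np.mean(
                        [sim.endpoint_offset_mm[i] for i in eidx])),
                    "speed_mult": sim.params.speed_mult,
                    "path_noise_sd": sim.params.path_noise_sd,
                    "overshoot_mm": sim.params.overshoot_mm,
                    "accel_jitter_sd": sim.params.accel_jitter_sd,
                })
    return pd.DataFrame(rows)
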