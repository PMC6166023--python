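"""Reader/writer for the per-trial per-frame text dialect.

Tab-separated; ``#``-prefixed ``key<TAB>value`` header lines carry the
camera and session parameters needed to recompute physical scale, followed
by a ``#``-prefixed column-name line and one record per frame::

    #participant_id\tS001
    #trial\t1
    #timestamp\t2024-01-01T00:00:00
    #image_width_px\t752
    ...
    #frame_index\ttime_s\tcentroid_x_px\t...
    0\t0.000000\t376.0000\t...

Writing then reading a series (and optional per-frame target statuses)
reproduces it exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .camera import CameraModel
from .segment import TargetStatus
from .series import CentroidSeries

_HEADER_KEYS = ("participant_id", "trial", "timestamp", "image_width_px",
                "image_height_px", "fov_width_mm", "fps")
_COLUMNS = ("frame_index", "time_s", "centroid_x_px", "centroid_y_px",
            "radius_px", "valid_flag", "interpolated_flag", "inside_left",
            "inside_right", "active_target", "subtask_id")


class TrialFileError(ValueError):
    pass


def _fmt(v: float) -> str:
    return "nan" if np.isnan(v) else repr(float(v))


def write_trial_file(path, series: CentroidSeries,
                     statuses: Optional[Sequence[TargetStatus]] = None,
                     participant_id: str = "", trial: int = 1,
                     timestamp: str = "1970-01-01T00:00:00") -> None:
    """Write a series (and optional statuses) losslessly to ``path``."""
    if statuses is not None and len(statuses) != len(series):
        raise TrialFileError("statuses length does not match series")
    cam = series.camera
    lines = [f"#participant_id\t{participant_id}",
             f"#trial\t{trial}",
             f"#timestamp\t{timestamp}",
             f"#image_width_px\t{cam.image_width_px}",
             f"#image_height_px\t{cam.image_height_px}",
             f"#fov_width_mm\t{_fmt(cam.fov_width_mm)}",
             f"#fps\t{_fmt(cam.fps)}",
             "#" + "\t".join(_COLUMNS)]
    for i in range(len(series)):
        if statuses is not None:
            st = statuses[i]
            status_part = (f"{int(st.inside_left)}\t{int(st.inside_right)}\t"
                           f"{st.active_target}\t{st.subtask_id}")
        else:
            status_part = "0\t0\t-\t-"
        lines.append(
            f"{i}\t{_fmt(i / cam.fps)}\t{_fmt(series.x[i])}\t"
            f"{_fmt(series.y[i])}\t{_fmt(series.radius[i])}\t"
            f"{int(series.valid[i])}\t{int(series.interpolated[i])}\t"
            + status_part)
    Path(path).write_text("\n".join(lines) + "\n")


def read_trial_file(path) -> Tuple[CentroidSeries,
                                   Optional[List[TargetStatus]], dict]:
    """Read a trial file.

    Returns ``(series, statuses, header)``; ``statuses`` is None when the
    file was written without target-status information.  Malformed lines,
    missing header keys, and non-consecutive frame indices raise
    :class:`TrialFileError` naming the offence.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise TrialFileError(f"{path}: empty trial file")
    header: dict = {}
    rows = []
    have_status = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if parts[0] == _COLUMNS[0]:
                continue  # column-name line
            if len(parts) != 2:
                raise TrialFileError(f"{path}:{lineno}: malformed header line")
            header[parts[0]] = parts[1]
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise TrialFileError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} fields, "
                f"got {len(fields)}")
        try:
            rows.append((int(fields[0]), float(fields[2]), float(fields[3]),
                         float(fields[4]), int(fields[5]), int(fields[6]),
                         int(fields[7]), int(fields[8]), fields[9],
                         fields[10]))
        except ValueError as exc:
            raise TrialFileError(f"{path}:{lineno}: {exc}") from None
        if fields[9] != "-":
            have_status = True
    for key in _HEADER_KEYS:
        if key not in header:
            raise TrialFileError(f"{path}: missing header key '{key}'")
    if not rows:
        raise TrialFileError(f"{path}: no frame records")
    for pos, row in enumerate(rows):
        if row[0] != pos:
            raise TrialFileError(
                f"{path}: frame_index must increase by 1 from 0; "
                f"got {row[0]} at record {pos}")
    cam = CameraModel(image_width_px=int(header["image_width_px"]),
                      image_height_px=int(header["image_height_px"]),
                      fov_width_mm=float(header["fov_width_mm"]),
                      fps=float(header["fps"]))
    n = len(rows)
    series = CentroidSeries(
        camera=cam,
        x=np.array([r[1] for r in rows]),
        y=np.array([r[2] for r in rows]),
        radius=np.array([r[3] for r in rows]),
        valid=np.array([bool(r[4]) for r in rows]),
        interpolated=np.array([bool(r[5]) for r in rows]))
    statuses = None
    if have_status:
        statuses = [TargetStatus(frame_index=i, inside_left=bool(r[6]),
                                 inside_right=bool(r[7]), active_target=r[8],
                                 subtask_id=r[9])
                    for i, r in enumerate(rows)]
    return series, statuses, header
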