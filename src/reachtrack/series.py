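"""Per-trial centroid time series — the tracker's raw output.

A :class:`CentroidSeries` holds one fiducial observation per acquired frame,
stored as dense numpy arrays for speed; :class:`FiducialObservation` is the
scalar per-frame view used at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .camera import CameraModel


@dataclass(frozen=True)
class FiducialObservation:
    frame_index: int
    centroid_px: Optional[tuple] = None   # (x, y), None when invalid
    radius_px: float = np.nan
    valid: bool = False
    interpolated: bool = False


@dataclass
class CentroidSeries:
    """Ordered per-frame fiducial observations for one trial.

    ``x``, ``y``, ``radius`` are NaN where ``valid`` is False.  Frame *i*
    was acquired at time ``i / camera.fps`` seconds.
    """

    camera: CameraModel
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.x)
        for arr, name in ((self.y, "y"), (self.radius, "radius"),
                          (self.valid, "valid"),
                          (self.interpolated, "interpolated")):
            if len(arr) != n:
                raise ValueError(f"length mismatch in field '{name}'")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self.x))

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_index / self.camera.fps

    def observation(self, i: int) -> FiducialObservation:
        if self.valid[i]:
            return FiducialObservation(
                frame_index=i, centroid_px=(float(self.x[i]), float(self.y[i])),
                radius_px=float(self.radius[i]), valid=True,
                interpolated=bool(self.interpolated[i]))
        return FiducialObservation(frame_index=i)

    def __iter__(self) -> Iterator[FiducialObservation]:
        return (self.observation(i) for i in range(len(self)))

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid)) if len(self) else 0.0

    @classmethod
    def from_positions(cls, camera: CameraModel, x, y,
                       radius_px: float = np.nan) -> "CentroidSeries":
        """All-valid series from position arrays (simulator convenience)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return cls(camera=camera, x=x, y=y,
                   radius=np.full(len(x), radius_px),
                   valid=np.ones(len(x), bool))
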