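"""Camera and fiducial-marker geometry.

The tracking system images a tabletop workspace with a fixed downward-facing
camera.  All physical scaling flows through a single factor, ``mm_per_px``,
derived from the camera's horizontal field of view and sensor width.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CameraModel:
    """Fixed overhead camera imaging the workspace.

    Parameters
    ----------
    image_width_px, image_height_px
        Sensor resolution in pixels.
    fov_width_mm
        Physical width of the imaged workspace, in millimetres.
    fps
        Frame rate, frames per second.
    """

    image_width_px: int = 752
    image_height_px: int = 480
    fov_width_mm: float = 183.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.fov_width_mm <= 0:
            raise ValueError("fov_width_mm must be positive")

    @property
    def mm_per_px(self) -> float:
        """Physical scale of one pixel (mm)."""
        return self.fov_width_mm / self.image_width_px


@dataclass(frozen=True)
class MarkerSpec:
    """Printed fiducial: a bright circle centred on a dark square.

    Gray levels are on the 0–255 scale.  The circle must be brighter than
    both the square it sits on and the workspace background so that a single
    intensity threshold can isolate it.
    """

    square_side_mm: float = 18.0
    circle_diameter_mm: float = 12.0
    square_intensity: float = 0.0
    circle_intensity: float = 230.0
    background_intensity: float = 20.0

    def __post_init__(self) -> None:
        if not self.circle_diameter_mm < self.square_side_mm:
            raise ValueError("circle must fit inside the square")
        if not (self.circle_intensity > self.square_intensity
                and self.circle_intensity > self.background_intensity):
            raise ValueError("circle must be the brightest element")

    def circle_radius_px(self, camera: CameraModel) -> float:
        return 0.5 * self.circle_diameter_mm / camera.mm_per_px

    def square_side_px(self, camera: CameraModel) -> float:
        return self.square_side_mm / camera.mm_per_px
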