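"""Task protocol: target geometry, subtask sequence, and timing constants.

A *trial* is six subtasks run in a fixed order — four with large targets,
one medium, one small — each consisting of five movements between a pair of
horizontally aligned squares, preceded by a 10 s rest on a central square.
The trained movement speed is 25.7 mm/s and the target centres are 138 mm
apart on the tabletop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

from .camera import CameraModel

SUBTASK_ORDER: Tuple[str, ...] = (
    "large1", "large2", "large3", "large4", "medium", "small",
)

#: target square side length per size class, in screen pixels
TARGET_SIDE_PX: Dict[str, int] = {"large": 100, "medium": 62, "small": 50}


def size_class(subtask_id: str) -> str:
    """``'large3'`` -> ``'large'`` etc."""
    return subtask_id.rstrip("0123456789")


@dataclass(frozen=True)
class Protocol:
    target_side_px: Dict[str, int] = field(
        default_factory=lambda: dict(TARGET_SIDE_PX))
    subtask_order: Tuple[str, ...] = SUBTASK_ORDER
    movements_per_subtask: int = 5
    rest_duration_s: float = 10.0
    rest_square_px: int = 100
    training_speed_mm_s: float = 25.7
    center_to_center_mm: float = 138.0

    def __post_init__(self) -> None:
        sides = [self.target_side_px[c] for c in ("large", "medium", "small")]
        if not (sides[0] > sides[1] > sides[2] > 0):
            raise ValueError("target sides must be positive and decrease "
                             "large > medium > small")
        if self.movements_per_subtask < 1:
            raise ValueError("movements_per_subtask must be >= 1")
        if self.training_speed_mm_s <= 0:
            raise ValueError("training_speed_mm_s must be positive")

    # ------------------------------------------------------------------
    # derived geometry (pixel coordinates: origin top-left, x right, y down)
    # ------------------------------------------------------------------
    def separation_px(self, camera: CameraModel) -> float:
        return self.center_to_center_mm / camera.mm_per_px

    def center_y(self, camera: CameraModel) -> float:
        return camera.image_height_px / 2.0

    def target_centers_px(self, camera: CameraModel) -> Tuple[
            Tuple[float, float], Tuple[float, float]]:
        """(left, right) target centres, vertically centred on screen."""
        cx = camera.image_width_px / 2.0
        cy = self.center_y(camera)
        half = 0.5 * self.separation_px(camera)
        left = (cx - half, cy)
        right = (cx + half, cy)
        side = max(self.target_side_px.values())
        if left[0] - side / 2 < 0 or right[0] + side / 2 > camera.image_width_px:
            raise ValueError("targets do not fit in the camera frame")
        return left, right

    def rest_center_px(self, camera: CameraModel) -> Tuple[float, float]:
        return (camera.image_width_px / 2.0, self.center_y(camera))

    def side_for(self, subtask_id: str) -> int:
        return self.target_side_px[size_class(subtask_id)]

    def roi_bounds(self, subtask_id: str, camera: CameraModel
                   ) -> Tuple[float, float, float, float]:
        """Inter-target corridor for the path-accuracy metric.

        Rectangle (x_lo, x_hi, y_lo, y_hi): height equal to the subtask's
        target side, vertically centred on the targets; width spanning from
        the left square's left edge to the right square's right edge.
        Boundary counts as inside.
        """
        (lx, cy), (rx, _) = self.target_centers_px(camera)
        h = self.side_for(subtask_id) / 2.0
        return (lx - h, rx + h, cy - h, cy + h)

    def rest_frames(self, camera: CameraModel) -> int:
        return int(round(self.rest_duration_s * camera.fps))


def point_in_square(x: float, y: float, center: Tuple[float, float],
                    side: float) -> bool:
    """Closed-square membership test (boundary counts as inside)."""
    return (abs(x - center[0]) <= side / 2.0
            and abs(y - center[1]) <= side / 2.0)
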