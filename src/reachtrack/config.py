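"""Run configuration: YAML overrides for camera, protocol, and analysis.

Unknown keys are rejected so that typos fail loudly.  Defaults reproduce
the published task constants (25.7 mm/s training speed, 183 mm field of
view, 30 fps, 100/62/50 px targets, 138 mm centre separation, 10 s rests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from .camera import CameraModel
from .protocol import Protocol


@dataclass(frozen=True)
class DetectionConfig:
    max_gap: int = 3
    circularity_min: float = 0.8
    radius_tol: float = 0.4


@dataclass(frozen=True)
class StatsConfig:
    icc_form: str = "2k"           # '2k' (agreement) or '3k' (consistency)
    stratify_subtask: bool = False

    def __post_init__(self) -> None:
        if self.icc_form not in ("2k", "3k"):
            raise ValueError("icc_form must be '2k' or '3k'")


@dataclass(frozen=True)
class RunConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    protocol: Protocol = field(default_factory=Protocol)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0


def _build(cls, overrides: dict, what: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(overrides) - allowed
    if unknown:
        raise KeyError(f"unknown {what} config key(s): {sorted(unknown)}")
    return cls(**overrides)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Build a RunConfig from a YAML file (or defaults when no path)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"camera", "protocol", "detection", "stats", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config section(s): {sorted(unknown)}")
    return RunConfig(
        camera=_build(CameraModel, raw.get("camera", {}), "camera"),
        protocol=_build(Protocol, raw.get("protocol", {}), "protocol"),
        detection=_build(DetectionConfig, raw.get("detection", {}),
                         "detection"),
        stats=_build(StatsConfig, raw.get("stats", {}), "stats"),
        seed=int(raw.get("seed", 0)))
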