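"""Synthetic data: rendered fiducial frames and simulated reaching trials.

Stands in for the camera and the study cohort.  Three layers:

* :func:`render_frame` — draw the fiducial marker (dark square, bright
  circle) at a sub-pixel position with anti-aliased edges and optional
  pixel noise; the oracle for the detection stage.
* :func:`simulate_trial` — generate the centroid series of one full trial
  (six subtasks, five movements each, 10 s rests) with known ground-truth
  segments, speeds, and endpoint offsets.  Between the target squares the
  horizontal speed is held constant at the commanded value; inside a target
  the hand decelerates smoothly to its reversal point and accelerates back
  out, so noiseless travel segments have exactly the commanded mean speed.
* :func:`simulate_cohort` / :func:`simulate_metric_matrix` — cohort-scale
  generation with linear age effects on the movement parameters, and a
  direct variance-components generator for reliability-recovery studies.

All randomness flows from explicit integer seeds via numpy Generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .camera import CameraModel, MarkerSpec
from .protocol import Protocol
from .segment import Segment
from .series import CentroidSeries

logger = logging.getLogger(__name__)

#: temporal smoothing (frames) of the lateral hand-jitter noise
_PATH_NOISE_SMOOTH_FRAMES = 5.0
_GRAY_MAX = 255.0


class SimulationError(RuntimeError):
    pass


# ======================================================================
# frame rendering
# ======================================================================

def _square_coverage(xs: np.ndarray, ys: np.ndarray, center: Tuple[float, float],
                     side: float) -> np.ndarray:
    """Exact area coverage of an axis-aligned square over unit pixels."""
    half = side / 2.0
    ox = (np.minimum(center[0] + half, xs + 0.5)
          - np.maximum(center[0] - half, xs - 0.5)).clip(0.0, 1.0)
    oy = (np.minimum(center[1] + half, ys + 0.5)
          - np.maximum(center[1] - half, ys - 0.5)).clip(0.0, 1.0)
    return ox * oy


def _disc_coverage(xs: np.ndarray, ys: np.ndarray, center: Tuple[float, float],
                   radius: float, supersample: int = 16) -> np.ndarray:
    """Area coverage of a disc over unit pixels; edge pixels supersampled."""
    d = np.hypot(xs - center[0], ys - center[1])
    cov = np.zeros_like(d)
    cov[d <= radius - 0.7072] = 1.0
    edge = (d > radius - 0.7072) & (d < radius + 0.7072)
    if edge.any():
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        ox, oy = np.meshgrid(off, off)
        ex, ey = xs[edge], ys[edge]
        inside = (np.hypot(ex[:, None] + ox.ravel()[None, :] - center[0],
                           ey[:, None] + oy.ravel()[None, :] - center[1])
                  <= radius)
        cov[edge] = inside.mean(axis=1)
    return cov


def render_frame(center_px: Sequence[float], camera: CameraModel,
                 marker: MarkerSpec, noise_sd: float = 0.0,
                 seed: Optional[int] = None) -> np.ndarray:
    """Render one gray frame with the marker centred at ``center_px``.

    Edges are anti-aliased by area coverage, so the intensity-weighted
    centroid of the rendered circle matches ``center_px`` to well under a
    tenth of a pixel.  Additive Gaussian noise (sd in gray levels) is
    applied last; values are clipped to [0, 255].  Deterministic for a
    given ``seed``.
    """
    cx, cy = float(center_px[0]), float(center_px[1])
    w, h = camera.image_width_px, camera.image_height_px
    half_sq = marker.square_side_px(camera) / 2.0
    for name, val, lim in (("x", cx, w), ("y", cy, h)):
        if val - half_sq < -0.5 or val + half_sq > lim - 0.5:
            raise ValueError(
                f"marker out of bounds: center {name} = {val:.2f} "
                f"(square half-side {half_sq:.2f}, image extent {lim})")
    img = np.full((h, w), marker.background_intensity, dtype=float)

    # work only inside the marker's bounding box
    pad = 2
    x0 = max(0, int(np.floor(cx - half_sq)) - pad)
    x1 = min(w, int(np.ceil(cx + half_sq)) + pad)
    y0 = max(0, int(np.floor(cy - half_sq)) - pad)
    y1 = min(h, int(np.ceil(cy + half_sq)) + pad)
    xs, ys = np.meshgrid(np.arange(x0, x1, dtype=float),
                         np.arange(y0, y1, dtype=float))
    box = img[y0:y1, x0:x1]
    a_sq = _square_coverage(xs, ys, (cx, cy), marker.square_side_px(camera))
    box[:] = box * (1 - a_sq) + marker.square_intensity * a_sq
    a_c = _disc_coverage(xs, ys, (cx, cy), marker.circle_radius_px(camera))
    box[:] = box * (1 - a_c) + marker.circle_intensity * a_c

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, _GRAY_MAX)


# ======================================================================
# subject parameters and age-effect model
# ======================================================================

@dataclass(frozen=True)
class SubjectParams:
    """Generative movement parameters of one subject (or one trial).

    ``speed_mult`` scales the trained speed of 25.7 mm/s; ``path_noise_sd``
    is the sd (mm) of smoothed lateral jitter; ``overshoot_mm`` the signed
    over/underreach past the target centre; ``accel_jitter_sd`` the sd
    (mm/s^2) of frame-to-frame acceleration fluctuation during cruise.
    ``trial_effect_sd`` is a convenience knob for between-trial
    perturbation when no full effect model is in play.
    """

    age: float = 70.0
    speed_mult: float = 1.0
    path_noise_sd: float = 0.0
    overshoot_mm: float = 0.0
    accel_jitter_sd: float = 0.0
    trial_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_mult <= 0:
            raise ValueError("speed_mult must be positive")
        for f in ("path_noise_sd", "accel_jitter_sd", "trial_effect_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def perturb_for_trial(self, rng: np.random.Generator) -> "SubjectParams":
        """Apply the generic between-trial perturbation (relative on the
        multiplicative knobs, additive in mm on the overshoot)."""
        s = self.trial_effect_sd
        if s == 0:
            return self
        return replace(
            self,
            speed_mult=max(0.2, self.speed_mult * (1 + rng.normal(0, s))),
            path_noise_sd=max(0.0, self.path_noise_sd * (1 + rng.normal(0, s))),
            accel_jitter_sd=max(0.0,
                                self.accel_jitter_sd * (1 + rng.normal(0, s))),
            overshoot_mm=self.overshoot_mm + rng.normal(0, s),
        )


@dataclass(frozen=True)
class ParamEffect:
    """Linear age model for one generative parameter:
    subject value = intercept + slope*age + N(0, between_sd);
    each trial adds N(0, within_sd)."""

    intercept: float
    slope: float = 0.0
    between_sd: float = 0.0
    within_sd: float = 0.0
    minimum: float = 0.0
    maximum: float = float("inf")

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("sds must be >= 0")

    def subject_value(self, age: float, rng: np.random.Generator) -> float:
        return self.intercept + self.slope * age + rng.normal(0, self.between_sd)

    def trial_value(self, subject_value: float,
                    rng: np.random.Generator) -> float:
        return min(self.maximum,
                   max(self.minimum,
                       subject_value + rng.normal(0, self.within_sd)))


def _default_effects() -> Dict[str, ParamEffect]:
    # Illustrative healthy-aging trends: everyone moves roughly twice the
    # trained speed, with speed, endpoint overreach, lateral jitter and
    # speed fluctuation all drifting upward over the 43-94 y span.
    # speed_mult is capped at 4.3 (~110 mm/s): the 30 fps frame rate cannot
    # represent a reversal inside the 50 px target much beyond that
    return {
        "speed_mult": ParamEffect(intercept=0.7, slope=0.03,
                                  between_sd=0.4, within_sd=0.12,
                                  minimum=0.2, maximum=4.3),
        "path_noise_sd": ParamEffect(intercept=1.5, slope=0.04,
                                     between_sd=0.9, within_sd=0.35),
        "overshoot_mm": ParamEffect(intercept=-1.0, slope=0.03,
                                    between_sd=1.0, within_sd=0.5,
                                    minimum=-4.0),
        "accel_jitter_sd": ParamEffect(intercept=20.0, slope=0.3,
                                       between_sd=8.0, within_sd=3.0),
    }


@dataclass(frozen=True)
class EffectModel:
    """Per-parameter linear age effects plus variance components."""

    effects: Dict[str, ParamEffect] = field(default_factory=_default_effects)
    seed: int = 0

    def subject_params(self, age: float, rng: np.random.Generator
                       ) -> Dict[str, float]:
        return {k: e.subject_value(age, rng) for k, e in self.effects.items()}

    def trial_params(self, subject_values: Dict[str, float], age: float,
                     rng: np.random.Generator) -> SubjectParams:
        vals = {k: self.effects[k].trial_value(v, rng)
                for k, v in subject_values.items()}
        vals["speed_mult"] = max(0.2, vals["speed_mult"])
        vals["path_noise_sd"] = max(0.0, vals["path_noise_sd"])
        vals["accel_jitter_sd"] = max(0.0, vals["accel_jitter_sd"])
        return SubjectParams(age=age, **vals)


# ======================================================================
# trial simulation
# ======================================================================

@dataclass
class TrialSimulation:
    """A simulated trial: the centroid series plus its ground truth."""

    series: CentroidSeries
    travel_segments: List[Segment]
    endpoint_segments: List[Segment]
    travel_mean_speed_mm_s: List[float]
    endpoint_offset_mm: List[float]
    params: SubjectParams

    @property
    def segments(self) -> List[Segment]:
        out = self.travel_segments + self.endpoint_segments
        return sorted(out, key=lambda s: (s.start, s.kind))


#: lateral-jitter aiming envelope ramp length (px): noise reaches full
#: amplitude this far outside a square edge, and is zero inside a square
_AIM_RAMP_PX = 80.0


def _movement(x0: float, dep_center: float, dep_half: float,
              arr_center: float, arr_half: float, overshoot_px: float,
              step_px: float, jitter_px: float,
              rng: np.random.Generator
              ) -> Tuple[List[float], List[float], int, int, int]:
    """Positions for one movement from rest at ``x0`` (a reversal point or
    the rest-square centre) to the reversal point inside the arrival square.

    Returns (positions appended after x0, lateral-noise envelope weights,
    index of first frame outside the departure square, arrival index,
    reversal index) — indices relative to the first appended frame.
    """
    direction = 1.0 if arr_center > x0 else -1.0
    x_rev_to = arr_center + direction * overshoot_px
    d_exit = (dep_center + direction * dep_half - x0) * direction
    if d_exit <= 0:
        raise SimulationError("movement start lies outside departure square")

    pos: List[float] = []
    x = x0
    # launch ramp: triangular speed profile completing inside the square
    n_up = max(0, int(np.floor(2.0 * d_exit / step_px - 1.0)))
    for k in range(1, n_up + 1):
        x += direction * step_px * k / (n_up + 1)
        pos.append(x)
    # cruise at commanded speed (plus optional jitter) until arrival
    min_step = 0.1 * step_px
    while abs(x - arr_center) > arr_half:
        s = step_px
        if jitter_px > 0:
            s = max(min_step, step_px + rng.normal(0.0, jitter_px))
        x += direction * s
        pos.append(x)
    arrival = len(pos) - 1
    # deceleration to the reversal point, monotone shrinking steps
    r = (x_rev_to - x) * direction
    if r <= 0:
        raise SimulationError(
            "overshoot places the reversal before the arrival frame; "
            "reduce |overshoot_mm| or the movement speed")
    n_down = max(1, int(np.ceil(2.0 * r / step_px)))
    w = n_down - np.arange(1, n_down + 1) + 0.5
    steps = r * w / w.sum()
    for s in steps:
        x += direction * s
        pos.append(x)
    pos[-1] = x_rev_to  # exact reversal point
    first_outside = next(
        i for i, p in enumerate(pos)
        if (p - (dep_center + direction * dep_half)) * direction > 0)
    # aiming envelope: zero inside either square, ramping to 1 mid-corridor
    weights = []
    for p in pos:
        d_dep = abs(p - dep_center) - dep_half
        d_arr = abs(p - arr_center) - arr_half
        weights.append(min(1.0, max(0.0, min(d_dep, d_arr) / _AIM_RAMP_PX)))
    return pos, weights, first_outside, arrival, len(pos) - 1


def simulate_trial(subject: SubjectParams, protocol: Protocol = None,
                   camera: CameraModel = None, seed: int = 0
                   ) -> TrialSimulation:
    """Simulate the centroid series of one complete trial.

    Raises :class:`SimulationError` if the commanded speed is so high that
    a travel segment would span fewer than 4 frames (acceleration would be
    undefined), or if the overshoot cannot fit inside a target square.
    """
    protocol = protocol or Protocol()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    mpp = camera.mm_per_px
    (lx, cy), (rx, _) = protocol.target_centers_px(camera)
    rest_x = protocol.rest_center_px(camera)[0]
    rest_half = protocol.rest_square_px / 2.0
    v_mm = protocol.training_speed_mm_s * subject.speed_mult
    step_px = v_mm / mpp / camera.fps
    o_px = subject.overshoot_mm / mpp
    # speed jitter sized so frame-to-frame acceleration sd = accel_jitter_sd
    jitter_px = (subject.accel_jitter_sd / (camera.fps * np.sqrt(2.0))
                 / mpp / camera.fps)

    # the reversal point must sit inside every target square, at least one
    # cruise step beyond the arrival frame's deepest possible penetration
    min_half = min(protocol.target_side_px.values()) / 2.0
    o_limit = min_half - 1.5 * step_px
    if o_limit <= 0:
        raise SimulationError(
            "movement speed too high for the smallest target at this "
            "frame rate")
    if abs(o_px) > o_limit:
        clamped = np.sign(o_px) * o_limit
        logger.warning(
            "overshoot %.2f mm not representable inside the smallest "
            "target at this speed; clamped to %.2f mm",
            subject.overshoot_mm, clamped * mpp)
        o_px = clamped

    xs: List[float] = [rest_x]
    envelope: List[float] = [0.0]
    rest_frames = protocol.rest_frames(camera)
    travel_segs: List[Segment] = []
    endpoint_segs: List[Segment] = []

    for sub in protocol.subtask_order:
        h = protocol.side_for(sub) / 2.0
        # rest hold on the central square
        xs.extend([rest_x] * rest_frames)
        envelope.extend([0.0] * rest_frames)
        # initiation: rest square -> left target reversal point
        pos, w, _, _, _ = _movement(xs[-1], rest_x, rest_half, lx, h, o_px,
                                    step_px, jitter_px, rng)
        xs.extend(pos)
        envelope.extend(w)
        cur, opp = (lx, h), (rx, h)
        for m in range(protocol.movements_per_subtask):
            base = len(xs)  # absolute index of the first appended frame
            pos, w, fo, arr, rev = _movement(xs[-1], cur[0], cur[1],
                                             opp[0], opp[1], o_px,
                                             step_px, jitter_px, rng)
            xs.extend(pos)
            envelope.extend(w)
            direction = "rightward" if opp[0] > cur[0] else "leftward"
            t = Segment(kind="travel", subtask_id=sub, segment_index=m,
                        start=base + fo, end=base + arr + 1,
                        direction=direction)
            if t.n_frames < 4:
                raise SimulationError(
                    f"travel segment of {t.n_frames} frames in {sub}; "
                    "speed too high for the frame rate")
            travel_segs.append(t)
            endpoint_segs.append(Segment(
                kind="endpoint", subtask_id=sub, segment_index=m,
                start=base + arr, end=base + rev + 1, direction=direction))
            cur, opp = opp, cur
        # return to the rest square centre
        pos, w, _, _, _ = _movement(xs[-1], cur[0], cur[1], rest_x,
                                    rest_half, 0.0, step_px, jitter_px, rng)
        xs.extend(pos)
        envelope.extend(w)
    xs.extend([rest_x] * 15)
    envelope.extend([0.0] * 15)

    x = np.asarray(xs)
    y = np.full_like(x, cy)
    if subject.path_noise_sd > 0:
        white = rng.standard_normal(len(x))
        smooth = gaussian_filter1d(white, _PATH_NOISE_SMOOTH_FRAMES,
                                   mode="reflect")
        # renormalize to unit variance, then scale to the requested sd;
        # the aiming envelope silences the jitter inside the squares so
        # that target arrival is unambiguous
        kernel_var = 1.0 / (2.0 * _PATH_NOISE_SMOOTH_FRAMES * np.sqrt(np.pi))
        noise_px = smooth / np.sqrt(kernel_var) * (subject.path_noise_sd / mpp)
        y = y + np.asarray(envelope) * noise_px

    marker = MarkerSpec()
    series = CentroidSeries.from_positions(
        camera, x, y, radius_px=marker.circle_radius_px(camera))

    speeds = np.hypot(np.diff(x), np.diff(y)) * mpp * camera.fps
    travel_speed = [float(np.mean(speeds[s.start:s.end - 1]))
                    for s in travel_segs]
    centers = {"rightward": rx, "leftward": lx}
    offsets = []
    for s in endpoint_segs:
        dsign = 1.0 if s.direction == "rightward" else -1.0
        extreme = np.max(dsign * x[s.start:s.end])
        offsets.append(float((extreme - dsign * centers[s.direction])
                             * mpp))
    return TrialSimulation(series=series, travel_segments=travel_segs,
                           endpoint_segments=endpoint_segs,
                           travel_mean_speed_mm_s=travel_speed,
                           endpoint_offset_mm=offsets, params=subject)


# ======================================================================
# cohort simulation
# ======================================================================

@dataclass(frozen=True)
class CohortSubject:
    participant_id: str
    age: float
    trial_params: Tuple[SubjectParams, SubjectParams]
    trial_seeds: Tuple[int, int]


@dataclass
class Cohort:
    subjects: List[CohortSubject]
    effects: EffectModel
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


def simulate_cohort(n_subjects: int, age_range: Tuple[float, float] = (43, 94),
                    effects: Optional[EffectModel] = None,
                    seed: int = 0, n_trials: int = 2) -> Cohort:
    """Draw a cohort: ages uniform over ``age_range``, per-subject movement
    parameters from the linear age-effect model, per-trial within-subject
    perturbations.  Reproducible for a given seed."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    effects = effects or EffectModel()
    if age_range[0] == age_range[1] and any(
            e.slope != 0 for e in effects.effects.values()):
        logger.warning("degenerate age range %s with nonzero slopes; "
                       "age effects are unidentifiable", age_range)
    root = np.random.SeedSequence(seed)
    age_ss, param_ss, trial_ss = root.spawn(3)
    age_rng = np.random.default_rng(age_ss)
    param_rng = np.random.default_rng(param_ss)
    ages = age_rng.uniform(age_range[0], age_range[1], size=n_subjects)
    trial_seeds = np.random.default_rng(trial_ss).integers(
        0, 2**31 - 1, size=(n_subjects, n_trials))
    subjects = []
    for i in range(n_subjects):
        sv = effects.subject_params(float(ages[i]), param_rng)
        tp = tuple(effects.trial_params(sv, float(ages[i]), param_rng)
                   for _ in range(n_trials))
        subjects.append(CohortSubject(
            participant_id=f"S{i + 1:03d}", age=float(ages[i]),
            trial_params=tp,
            trial_seeds=tuple(int(s) for s in trial_seeds[i])))
    return Cohort(subjects=subjects, effects=effects, seed=seed)


def simulate_subject_trials(subject: CohortSubject,
                            protocol: Protocol = None,
                            camera: CameraModel = None
                            ) -> List[TrialSimulation]:
    """Run :func:`simulate_trial` for each of a cohort subject's trials."""
    return [simulate_trial(p, protocol, camera, seed=s)
            for p, s in zip(subject.trial_params, subject.trial_seeds)]


# ======================================================================
# direct variance-components simulation (reliability recovery)
# ======================================================================

def sigma_b_for_icc2k(icc: float, sigma_w: float = 1.0, k: int = 2) -> float:
    """Between-subject sd giving a target ICC(2,k) with no trial effect.

    With value_ij = mu + b_i + e_ij, ICC(2,k) = sb^2 / (sb^2 + sw^2/k).
    """
    if not 0 < icc < 1:
        raise ValueError("icc must be in (0, 1)")
    return float(sigma_w * np.sqrt(icc / (k * (1.0 - icc))))


def simulate_metric_matrix(n_subjects: int, sigma_b: float, sigma_w: float,
                           k: int = 2, mu: float = 0.0,
                           trial_shifts: Optional[Sequence[float]] = None,
                           seed: int = 0) -> np.ndarray:
    """Subjects x trials metric matrix with known variance components:
    value_ij = mu + shift_j + b_i + e_ij."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, size=(n_subjects, 1))
    e = rng.normal(0.0, sigma_w, size=(n_subjects, k))
    out = mu + b + e
    if trial_shifts is not None:
        out = out + np.asarray(trial_shifts, float)[None, :]
    return out
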