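# Methods

This note records the models, conventions, and numerical choices behind
`reachtrack`, and what the synthetic experiments do and do not establish.

## Coordinate and unit conventions

Image coordinates have their origin at the top-left pixel centre, x
rightward, y downward, pixel centres at integer coordinates. The physical
scale is `mm_per_px = fov_width_mm / image_width_px`; the default camera
is 752 × 480 px with a 183 mm horizontal field of view at 30 fps, giving
0.2434 mm/px. The camera resolution is a package default (that of a
common industrial USB sensor) and is configurable; only the 183 mm field
of view and 30 fps are task constants. Frame ranges are half-open
`[start, end)` with 0-based indices. All "inside a square/rectangle"
tests are closed: a point exactly on the boundary is inside.

## Frame synthesis

`render_frame` composes background, dark square, and bright circle by
area-coverage anti-aliasing: the square's coverage of each pixel is exact
(axis-aligned overlap); the circle's edge pixels are super-sampled on a
16 × 16 grid. Additive Gaussian pixel noise is applied last and clipped
to [0, 255]. This yields intensity-weighted centroids accurate to a few
hundredths of a pixel, which is what makes the sub-pixel detection
accuracy tests meaningful. Tests validate the renderer against an
independent dense rasterization oracle.

## Fiducial detection

Calibration sweeps every integer gray threshold across the calibration
frame's intensity range. A threshold is valid when binarization yields
exactly one non-speck connected component (specks below 9 px are ignored)
and that component is circle-like: area at least that of a half-radius
disc, equivalent radius within ±40% of expected, roundness ≥ 0.8. The
working threshold is the median of the longest contiguous valid run. The
strict "exactly one component" rule makes the valid range end just above
the background gray level, which is also where a live system would start
to fail.

**Roundness.** The conventional isoperimetric circularity 4πA/P² is
biased upward on a discrete grid: with every perimeter estimator
available (chain-code or Crofton), a filled square of the fiducial's area
scores 0.82–0.89, defeating a 0.8 cutoff. We therefore score components
by circumscribed-circle roundness, `area / (π · r_max²)` with `r_max` the
farthest component pixel from the centroid plus half a pixel. A disc
scores ≈ 0.95, a square 2/π ≈ 0.64, so the same 0.8 cutoff separates them
with margin. Among surviving candidates the highest roundness wins (ties
broken by area). The published system's circle-detection algorithm is not
specified; connected-component analysis with a roundness score is our
substitute for it.

The reported position is the intensity-weighted centroid of the winning
component's pixels, which is what gives sub-pixel precision; the radius is
the equivalent-area radius. Dropouts of up to `max_gap` frames (default
3, ≈ 0.1 s) are bridged by linear interpolation and flagged; longer runs
stay invalid. Vertical (out-of-plane) position is deliberately not
estimated from the marker's apparent size.

## Task model and segmentation

The state machine is event-driven: within a subtask, the first frame
whose centroid lies inside the active target square is an arrival, which
activates the opposite square. A subtask comprises an initiation arrival
(from rest to the left target) plus five movement arrivals; frames
outside the initiation-to-final-arrival window are labelled rest. Rest
blocks are therefore delimited by the arrival sequence, not by timing or
motion thresholds — the 10 s rest duration is used only by the generator.

Travel segments run from the first frame strictly after the last frame
inside the departure square through the arrival frame inclusive; the
arrival frame is shared with the endpoint segment, which runs from
arrival to the horizontal direction-reversal frame. Reversal is the first
sign change of frame-to-frame x-displacement after arrival (displacements
below 1e-12 px are treated as stationary and absorbed), and the reversal
frame is the extreme-x frame of that run; if the centroid exits the
square still moving forward, the endpoint is missing — logged and
excluded from offset averages. A complete trial always yields 30 travel
segments; endpoint segments can be fewer. The segment-tiling audit in the
tests confirms that travel and endpoint segments cover the analyzed
frames exactly once, with arrival frames as the only (deliberate)
junction points.

## Metrics

Instantaneous speed uses two consecutive frames; instantaneous
acceleration is the difference of two consecutive speeds times fps, so
each sample spans four raw frames. Acceleration is averaged as a mean
absolute value: over a segment that starts and ends near the commanded
speed, a signed mean would cancel to ≈ 0 and carry no information, while
the mean magnitude measures speed fluctuation. Speed error is computed
per travel segment from the segment-mean speed, then averaged across the
subtask's segments. Center offset is projected on the travel direction so
overreach is positive for both leftward and rightward approaches. IPA
counts only travel-segment frames: endpoint frames lie inside a target
square — inside the corridor by construction — and would only dilute the
measure; the denominator is the subtask's valid travel frames.

## Trial simulator

Between the squares the horizontal speed is held constant at the
commanded value (`25.7 mm/s × speed_mult`); inside a square the hand
decelerates along a monotone shrinking-step profile to its reversal point
(`target centre + overshoot`) and launches back out along a triangular
ramp that completes before the square's edge. Consequences, by
construction: every noiseless travel segment's mean speed equals the
commanded speed to machine precision, every endpoint offset equals the
commanded overshoot exactly, and the segmentation stage recovers the
generator's ground-truth frame ranges identically. A full minimum-jerk
profile was considered and rejected: its mean speed over the travel
portion depends on the segment's extent, which would turn exact anchor
checks (0% and 100% speed error) into approximate ones.

Two noise processes ride on top. Speed fluctuation adds white noise to
the per-frame cruise step, scaled so that the sd of frame-to-frame
acceleration equals `accel_jitter_sd` (mm/s²); the resulting mean
absolute acceleration is `accel_jitter_sd·√(2/π)`. Lateral jitter is
Gaussian white noise smoothed with a 5-frame Gaussian kernel (hand paths
wander slowly; unsmoothed white noise would absurdly inflate Euclidean
speeds), renormalized to sd `path_noise_sd` (mm), and multiplied by an
*aiming envelope*: zero inside either square, ramping linearly to full
amplitude 80 px into the corridor. The envelope models participants
converging on the target they are looking at; operationally it guarantees
that the x-based arrival the generator plans coincides with the 2-D
point-in-square arrival the state machine detects, for every target size.
Lateral jitter therefore perturbs the corridor (IPA, speed) but never
endpoint geometry.

The frame rate bounds representable speeds: a reversal must sit at least
~1.5 cruise steps inside the smallest (50 px) square, so commanded speeds
above ≈ 110 mm/s raise an error and overshoot draws beyond the
representable range are clamped with a warning. This mirrors the physical
system, whose 30 fps likewise restricted usable participant speed.

## Cohort model

Each generative parameter follows a linear age model: subject value =
intercept + slope·age + N(0, between_sd), with each trial adding
N(0, within_sd), truncated to its physical range. Ages are uniform over
the requested range (default 43–94 y). Age acting linearly matches the
linear-regression analyses the pipeline performs and makes slope recovery
well-posed. The default effect sizes are illustrative, chosen so that a
typical subject moves at roughly twice the trained speed (≈ 100% speed
error in the young, several hundred percent in the old), endpoint
overreach and speed fluctuation drift mildly upward with age, and lateral
jitter is large enough that path accuracy is the least reliable metric;
they are not calibrated to any cohort's printed summary statistics. All
randomness flows from explicit integer seeds through spawned numpy
generators; every simulation is bit-reproducible.

For reliability-recovery experiments the trajectory layer is unnecessary:
`simulate_metric_matrix` draws subject × trial values directly as
μ + b_i + e_ij with chosen variance components, for which the theoretical
agreement ICC for k-trial averages is σb²/(σb² + σw²/k) (closed form
inverted by `sigma_b_for_icc2k`).

## Reliability statistics

The subjects × trials matrix of per-subject means (subtasks pre-averaged;
a per-subtask mode is available) feeds a two-way ANOVA without
replication. The headline reliability is the two-way agreement form for
k-trial averages, ICC(2,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n); the
consistency form ICC(3,k) = (MS_R − MS_E)/MS_R is reported alongside,
since the two labels are often conflated and the agreement form is the
stricter (it penalizes a systematic trial shift). The ICC(2,k) confidence
interval follows the F-based single-rater procedure (Shrout–Fleiss /
McGraw–Wong, with the Satterthwaite denominator df) Spearman–Brown-scaled
to average measures; ICC(3,k) uses the exact F pivot. Both point
estimates and intervals are verified in the tests against an independent
implementation (pingouin) and against hand-computed worked matrices.
Pearson trial-vs-trial correlations carry Fisher-z 95% intervals
(coverage verified by simulation at ρ = 0.85, n = 111). Subjects with any
missing cell are dropped listwise per metric. Significance conventions:
p < 0.05 for regressions, no multiple-testing correction. Degenerate
inputs are handled explicitly: zero between-subject variance reports
ICC 0 with a warning; perfect agreement reports ICC 1 with a degenerate
interval; |r| = 1 yields a degenerate Fisher interval.

## Problem sizes in the shipped experiments

The test suite and acceptance script use: 200 rendered frames for the
detection-accuracy property; 500 replicates of n = 111, k = 2 metric
matrices per ICC set-point {0.56, 0.61, 0.84, 0.85, 0.86}; 40-subject
two-trial trajectory cohorts for age-slope recovery; 500 null
simulations for the type-I-error check; 1000 replicates for Fisher-z
coverage. These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances (e.g. ±0.03 on the ICC mean, 93–97% on coverage)
while keeping a full run to tens of seconds.

## Known limitations

* The simulator is kinematic, not biomechanical: no tremor, no submovement
  structure, no pathology, no vertical motion. Passing tests demonstrate
  that the *pipeline* measures what the generator encodes — not that the
  generator reproduces real hands.
* Real video brings illumination gradients, motion blur, and reflections
  that the renderer does not model; the detection accuracy figures are
  upper bounds for clean imagery.
* AVI input is supported only insofar as the installed imageio backend
  can decode it; PNG frame sequences are the tested path.
* The aiming envelope makes lateral noise vanish inside targets, so
  simulated endpoint scatter comes solely from the overshoot parameter.
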