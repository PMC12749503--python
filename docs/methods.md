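# Methods

`kinescore` scores how faithfully a recorded exercise performance matches a
reference demonstration, working entirely from 33-landmark pose-keypoint
time series (the output format of markerless full-body pose trackers).
This note documents the model, the tunable parameters, the synthetic-data
generator, the numerical choices, and the known limitations.

## Input model

A recording is a sequence of frames, each holding 33 landmarks with
normalized coordinates `x, y` (fractions of the frame width and height,
`y` increasing downward), an optional relative depth `z`, and a visibility
confidence in [0, 1].  The video metadata (`Width`, `Height`,
`AverageFPS`, `TotalNumberOfFrames`) travels with the landmark data; the
machine-readable schema ships in `src/kinescore/data/pose_schema.json`.
`z` is read and preserved for round-tripping but unused: every computation
in the package is planar, matching the single-view recording setting the
method is designed for.

## Preprocessing

1. **Pixel conversion.** `X = x·width`, `Y = y·height`.
2. **Fixed maximum bounding box.** Per-frame boxes over the
   visibility-passing landmarks (extremes ± a buffer) jitter with every
   small detection error, so the whole recording is assigned one box — the
   union of all per-frame boxes — as a constant spatial reference.  The
   buffer defaults to 5% of the larger frame dimension.
3. **Box normalization.** `X_final = (X − box.min_x)/box.width`, similarly
   for `Y`.  This removes camera framing and subject placement effects for
   trajectory-level comparison.  Joint angles are **not** computed on
   box-normalized coordinates: dividing the two axes by different box
   extents is an anisotropic scaling and distorts angles (asserted as a
   property test).  Angles are computed on pixel coordinates, which the
   angle's similarity-invariance makes equivalent to any isotropically
   scaled frame.
4. **Visibility filling.** Landmarks with visibility below a threshold
   (default 0.5) are linearly interpolated across gaps of at most
   `max_gap` frames (default 5); longer gaps leave the landmark invalid
   and excluded downstream.
5. **Smoothing.** A centered moving average (default window 5 frames,
   shrinking at the edges) applied to angle trajectories.  Window 1
   disables it.

## Kinematic features

The angle at joint `(proximal, vertex, distal)` is

    a = p_proximal − p_vertex,  b = p_distal − p_vertex
    θ = arccos( a·b / (‖a‖‖b‖) )  ∈ [0°, 180°]

which is invariant to global translation, rotation and uniform scaling —
the property that makes angular features robust to viewpoint and jitter.
An optional signed mode (`atan2` of cross and dot products, range
[0°, 360°)) admits reflex angles such as hyperextension; the default is
the folded arccos form.  The joint → landmark-triplet table ships as an
editable YAML (`data/joints.yaml`): elbow = (shoulder, elbow, wrist),
shoulder = (hip, shoulder, elbow), hip sagittal = (shoulder, hip, knee),
hip frontal = (contralateral hip, hip, knee), knee = (hip, knee, ankle),
for both sides.

Derived quantities:

* **Range of motion** `ROM = θ_max − θ_min` over the valid frames.
* **Angular velocity** by central differences,
  `v(t) = (θ(t+1) − θ(t−1))·fps/2`, with one-sided differences at the two
  boundary frames.  The central stencil is second-order accurate and
  halves high-frequency noise relative to forward differences.
* **Standardization** `(x − μ)/σ` with the population standard deviation;
  constant signals return all-zeros with a flag rather than raising,
  because a flat trajectory carries no shape to correlate.  (Across-
  repetition summaries use the *sample* sd, n−1 — a different statistical
  context, deliberately not unified.)
* **Across-repetition summaries**: per-cycle ROM and mean |velocity| of
  the accepted cycles, reported mean ± sample sd; a single cycle reports
  sd 0 with a flag.

## Repetition segmentation and counting

One repetition is one trough → peak → trough cycle of the exercised
joint's angle trajectory.  Peaks are local maxima with prominence at least
20% of the observed signal range (making counting invariant to affine
rescaling) separated by at least 0.25 s; troughs come from running the
same detector on the negated signal; plateaus resolve to their midpoint.
The sequence boundaries act as virtual troughs so the first and last
cycles of a recording are not lost.  Counting accuracy is

    error % = |detected − actual| / actual × 100

with the reference recording's detected count serving as "actual" when
scoring a pair.

A **stability filter** marks cycles unusable for biomechanical summaries
(they still count): a cycle is accepted only if ≥ 80% of its frames are
valid, its boundary angles return below the midpoint between its trough
and peak levels (a full cycle, not a truncated boundary fragment), and no
frame-to-frame jump exceeds 20°.

For noisy recordings the package reports ROM as the across-repetition
mean per-cycle ROM of the accepted cycles rather than the global
max − min excursion: the global extremes of a noisy signal are inflated
by the maximum of the noise over all frames, whereas the per-cycle mean
averages that inflation away and matches how per-repetition biomechanics
are reported clinically.

## Pairing, DTW and NCC

User and reference repetitions are paired **ordinally** (i-th with i-th,
up to the smaller count; surplus cycles are reported unmatched).  Within a
pair, the two angle windows are edge-padded to a common length with their
peaks at the same index.

Both windows are standardized, then aligned with **dynamic time warping**:
the classic dynamic program with squared pointwise cost and step set
{(1,0), (0,1), (1,1)}, no window constraint; the distance is the square
root of the accumulated cost along the optimal path, so identical series
are at distance 0, a uniformly time-dilated copy is at distance 0, and for
equal lengths the distance is bounded by the Euclidean distance.
Backtracking ties break deterministically (diagonal first, then the step
consuming the user series).  DTW is not a metric (no triangle
inequality); only symmetry and the identity property are relied on.

The user window is projected onto the reference timeline along the DTW
path (samples mapped to the same reference index are averaged) and the
warped pair is compared with **normalized cross-correlation** over lags
τ ∈ [−max_lag, max_lag], max_lag defaulting to 25% of the window length.
The correlation at each lag is the Pearson correlation of the two
overlapping segments, with means and population sds taken over the
overlap.  This estimator is bounded (|R(τ)| ≤ 1 by Cauchy–Schwarz), peaks
at exactly 1 at lag 0 for identical signals, and is invariant to positive
affine transforms of either signal.  An alternative normalization that
reuses the full-series moments at every lag was considered and rejected:
it can exceed 1 whenever the overlap covariance beats the global variance,
which breaks the bound that the score's interpretation rests on.

Ordering rationale: warping first and correlating second follows the
pipeline's design (alignment absorbs speed differences; NCC then measures
shape agreement of the aligned curves).  The DTW distance of each pair is
reported alongside R_max so the un-warped disagreement stays visible.

## Composite Action Score

Per-repetition maxima R_max^(i) aggregate to `S = mean_i R_max^(i)`; with
the repetition count error `e` (percent) the composite is

    combined = 100 · (w_sim · max(S, 0) + w_rep · max(1 − e/100, 0)) / (w_sim + w_rep)

with equal default weights.  The linear clamped blend is this package's
own formulation of "similarity combined with repetition accuracy": it is
monotone in both components, spans [0, 100], and every component is
reported separately so the composite stays auditable.  When several
joints are scored, each joint gets its own S and the overall similarity
is the unweighted cross-joint mean; the repetition error comes from the
first-listed (driving) joint.

## Feedback conventions

Two sign conventions coexist in clinical comparison tables and both are
preserved, labelled on every field, rather than unified: range
differences are *demonstration − subject* (positive = subject moved
through less range), extreme-angle differences are *user − ideal*
(positive = user exceeded the ideal extreme).  Feedback text uses a fixed
template family — "No significant deviation" within a 5° tolerance
(boundary inclusive), "<joint> flexing X° less than demo" for range
shortfalls, "<joint> extending X° more than demo" for over-extension.
Report rounding is half-away-from-zero, to integers (summary style) or
one decimal (validation style).  ROM agreement against goniometric
measurement is the relative deviation |automated − clinician|/clinician ×
100.

## Synthetic motion generator

The generator exists so every stage is testable against known ground
truth without recorded video.

* **Angle cycles** are raised cosines,
  `θ(t) = baseline + (rom/2)(1 − cos(2π·n_reps·t/T + phase))`, so each
  trajectory starts and ends at its trough (making trough-peak-trough
  segmentation exact at the boundaries), has exactly `n_reps` maxima, and
  analytic extremes `baseline` and `baseline + rom`.
* **Forward kinematics** renders the cycles through a planar skeleton
  whose segment lengths follow standard anthropometric ratios (fractions
  of a 600-pixel stature, editable in `data/skeleton.yaml`).  Each driven
  joint rotates its distal segment about the vertex so the *measured*
  triplet angle equals the assigned angle exactly — the generator and the
  measurement are inverse by construction, verified to 1e-6°.
* **Corruption** reproduces the disturbance taxonomy of real pose
  tracking: i.i.d. Gaussian jitter per landmark coordinate (σ in
  normalized units; σ = 0.0015 corresponds to ≈ 1.35° of angle noise on
  the default skeleton), a shared sinusoidal drift of all landmarks
  (pure translation — angles provably untouched), and bursty visibility
  dropout (Bernoulli onset, geometric burst length).  Everything is
  seeded; identical spec + seed gives byte-identical output.

What the generator does **not** emulate: anatomical out-of-plane motion,
perspective foreshortening, limb self-occlusion correlated with pose,
soft-tissue artifacts, and detector biases that correlate across
neighbouring landmarks.  Passing the recovery grid therefore demonstrates
correctness of the computational pipeline under known, well-behaved
corruption — not detector-level accuracy on real video.

## Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| visibility threshold | 0.5 | — | midpoint of the confidence scale |
| interpolation max gap | 5 | frames | ~0.1–0.2 s of occlusion |
| box buffer | 5% | of larger frame dim | limb excursions near box edges |
| smoothing window | 5 | frames | noise ↓ ~√5 with ≤ ~1° peak flattening at 30 fps |
| peak prominence | 20% | of signal range | affine-invariant counting |
| peak min distance | 0.25 | s | faster cycles are not physiological |
| stability: valid fraction | 0.8 | — | tolerates brief dropout per cycle |
| stability: max jump | 20 | °/frame | ~3× the steepest clean per-frame change |
| NCC max lag | 25% | of window | residual phase after warping is small |
| score weights | 1, 1 | — | neither component privileged |
| feedback tolerance | 5 | ° | clinical reporting granularity |

## Problem sizes used in tests

The recovery grid draws 100 seeded configurations (repetitions 1–10, ROM
30–120°, 30/60 fps, 2 s per repetition, jitter σ = 0.0015 ≈ 1.35°
angle-equivalent, 0.5% dropout onset, 10 px drift), rendering each both
clean and corrupted — about 60 000 frames total, a size chosen to
exercise every fps/ROM/count regime while keeping the whole suite fast.
Oracle checks enumerate all DTW warping paths for series up to length 6
(200 random pairs).

## Known limitations

* Strictly planar: out-of-plane motion projects onto the camera plane and
  biases angles; multi-view or depth fusion is out of scope.
* The arccos angle folds reflex angles above 180° back; the signed mode
  exists but needs a per-joint reference orientation chosen by the user.
* Ordinal repetition pairing assumes both recordings start with the same
  cycle; a missed first repetition shifts all subsequent pairs.
* The composite score's clamping hides *how* anti-correlated a movement
  is below S = 0; the per-repetition values remain in the report.
* Boundary cycles rely on the virtual-trough rule; a recording cut
  mid-cycle yields a truncated segment that the stability filter rejects
  from summaries but that still affects the count.
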