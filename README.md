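# kinescore

Automated action scoring for physical-therapy exercises, from markerless
pose-keypoint time series.

Home-based rehabilitation exercises are mostly performed unsupervised, and
visual assessment of joint angles by eye is imprecise.  Markerless human
pose estimation yields per-frame coordinates of 33 anatomical landmarks;
`kinescore` turns such keypoint sequences into objective movement
assessments for clinicians and patients: joint angles, range of motion
(ROM), angular velocity, repetition counts, and a composite *Action Score*
comparing a patient's recording against a reference demonstration.

## Method at a glance

* **Angular features.** The angle at a joint triplet
  (proximal, vertex, distal) is
  `θ = arccos(a·b / ‖a‖‖b‖)` with `a = p_prox − p_vert`,
  `b = p_dist − p_vert` — invariant to translation, rotation and uniform
  scale, hence robust to camera placement and detector jitter.
  `ROM = θ_max − θ_min`; velocity by central differences
  `v(t) = (θ(t+1) − θ(t−1))·fps/2`.
* **Stabilisation.** Keypoints are re-normalized to a *fixed maximum
  bounding box* (the union of all per-frame boxes), suppressing the
  frame-to-frame box jitter of per-frame normalization; low-visibility
  landmarks are interpolated across short gaps.
* **Repetitions.** One repetition is a trough→peak→trough cycle of the
  exercised joint's angle trajectory; peaks are prominence-filtered local
  maxima, troughs come from the negated signal, and counting accuracy is
  `error % = |detected − actual| / actual × 100`.
* **Similarity.** User and reference repetitions are paired ordinally and
  peak-aligned; standardized windows are aligned by dynamic time warping
  (DTW) and compared with lagged normalized cross-correlation (NCC).  The
  per-repetition maxima `R_max ∈ [−1, 1]` average to the similarity
  `S = (1/N) Σ R_max^(i)`, and

      Action Score = 100 · (w_sim·max(S,0) + w_rep·max(1 − error/100, 0)) / (w_sim + w_rep)

* **Feedback.** Clinician-style deviation tables ("Right knee flexing
  110° less than demo") with documented sign conventions and rounding.

A seeded synthetic-motion generator (raised-cosine angle cycles rendered
through a planar anthropometric skeleton, with optional jitter, drift and
visibility dropout) provides ground-truth-known recordings for testing
and demonstration.  See `docs/methods.md` for the full model description.

## Worked example

Render a 10-repetition reference squat (knee 50–170°) and a noisy user
recording that manages only 9 shallower repetitions (knee 50–130°), then
score them:

```sh
kinescore simulate reference.yaml -o reference.json
kinescore simulate user.yaml -o user.json
kinescore score user.json reference.json --joint right_knee -o report.json
```

where `user.yaml` is

```yaml
exercise: bodyweight_squat
driven:
- joint: right_knee
  baseline: 50.0
  rom: 80.0
  n_reps: 9
fps: 30.0
duration: 20.0
noise_sigma: 0.0015
dropout_prob: 0.005
seed: 7
```

(and `reference.yaml` the same with `rom: 120`, `n_reps: 10`, no noise).
The score command prints

```
similarity S=0.999  rep error=10.0%  Action Score=94.9
```

and `report.json` contains, for the scored joint:

```json
{
 "similarity": 0.9985070030467192,
 "rep_error_percent": 10.0,
 "combined_score": 94.92535015233597,
 "user_rom_deg": 80.95939172883001,
 "reference_rom_deg": 118.7974578284915,
 "feedback": "Right knee flexing 38° less than demo",
 "user_reps_detected": 9,
 "reference_reps_detected": 10
}
```

Reading: the *shape* of each repetition matches the demonstration almost
perfectly (S ≈ 0.999 — the user moves smoothly, just through a smaller
range), one repetition is missing (9 of 10 → 10% count error), and the
composite blends the two into 94.9/100.  The feedback line quantifies the
ROM shortfall (≈ 38° less knee excursion than demonstrated, measured on
the noisy signal).  Per-repetition `R_max`, best lags and DTW distances
are in the full report for audit.

Other commands: `kinescore validate` (schema/invariant checks),
`kinescore features` (per-frame angle/velocity CSV and per-repetition
ROM ± sd summaries), `kinescore reps` (segment table CSV).  All pipeline
parameters live in one YAML config (`-c config.yaml`) and are echoed into
every report.

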