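# Methods

`napscope` analyses sleep movements from contactless video by reducing a
stream of 2D body-pose landmarks to joint-angle time series, per-session
movement indices, and a nonparametric between-condition comparison. This
note records the models, the defaults and why they were chosen, what the
synthetic-session generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Joint-angle model

A pose backend (e.g. a BlazePose-family estimator) supplies, per video
frame, up to 12 named landmarks — shoulders, elbows, wrists, hips, knees
and ankles, both sides — as normalized image coordinates in [0, 1] with
optional visibility scores. Each monitored angle is defined by a triplet
(A, B, C) with vertex B; after converting to pixel coordinates
(x·width, y·height), the angle is

θ = acos( (AB · BC) / (‖AB‖ ‖BC‖) ) · 180/π,  AB = B − A, BC = C − B.

θ is the angle *between the limb vectors*, so a perfectly straight limb
scores 0° and the familiar interior angle at the vertex is 180 − θ. θ is
invariant to translation, rotation and uniform scaling but **not** to
anisotropic scaling: pixel-space and normalized-space angles differ
whenever the frame is not square, and the pixel-space definition is the
one used throughout. The acos argument is clamped to [−1, 1] to absorb
floating-point overshoot near collinearity; zero-length limb vectors
raise a degenerate-geometry error rather than return a silent 0, which
would corrupt the movement indices downstream.

### Triplet table

Only the elbow (shoulder–elbow–wrist) and knee (hip–knee–ankle) triplets
are canonical. The shipped table (package data `data/topology.yaml`,
user-replaceable) completes the set same-side:

| angle | A | B (vertex) | C |
|---|---|---|---|
| shoulder | hip | shoulder | elbow |
| elbow | shoulder | elbow | wrist |
| wrist | elbow | wrist | hip |
| hip | shoulder | hip | knee |
| knee | hip | knee | ankle |
| ankle | knee | ankle | hip |

Wrist and ankle vertices have a single skeletal neighbour within the
12-point set, so their angles close against the same-side hip — an
explicit convention of this package, not an anatomical standard, chosen
so that all 12 labelled angles are computable from the 12 points alone.
Users tracking an extended topology can substitute their own third
points via a custom YAML table.

Frames are screened per landmark: a landmark is usable when present with
visibility ≥ `min_visibility` (default 0.5; visibility defaults to 1
when the backend supplies none). Angles with an unusable landmark are
recorded as missing, never interpolated at the frame level.

## Movement indices

Each angle series is segmented into **stable segments**: maximal runs in
which every retained sample stays within `tolerance_deg` of the
segment's running median. The scan is left-to-right; a sample out of
band starts a new segment only when the *next* present sample is also
out of band. An isolated excursion is discarded as impulse noise — a
deliberate softening of a strict every-sample-in-band rule, because a
single >5σ noise spike would otherwise split a genuine dwell in two and
corrupt the stable-time indices, while a real repositioning event always
produces consecutive out-of-band samples. Segment boundaries land on the
first sample of the new level, so a true event is localized to within
one frame period. Segments shorter than `min_duration_s` are dropped;
missing runs longer than `gap_fill_s` are never bridged and instead
split the segmentation (long occlusions must not fabricate stability).
Shorter gaps are linearly interpolated. Segment level is the median of
its samples (robust to residual spikes).

Indices per angle and session:

* **n_changes** — transitions between consecutive stable segments with
  level shift ≥ `delta_deg`;
* **max_change_deg** — the series range (max − min over present
  samples). Note the range estimator is biased upward under noise by the
  extremes of the noise distribution (≈ 2 × 2.9σ for sessions of a few
  thousand frames); the largest single between-segment shift is exported
  alongside as `max_event_change_deg`;
* **max_stable_s / min_stable_s** — longest/shortest stable-segment
  durations, with segment end defined as last sample time + 1/fps
  (sample-and-hold), so a constant 300 s series yields one 300 s
  segment;
* **duration_s** — the session span, identical across the 12 rows.

Defaults: `tolerance_deg` 5°, `delta_deg` 10°, `min_duration_s` 2 s,
`gap_fill_s` 1 s, fps 30 when timestamps are absent. No published
thresholds exist for "stable" and "change" in this setting; these values
make the detector insensitive to ~1° frame noise while catching
repositioning events of 10° and larger, and they are all explicit,
test-covered configuration.

## Statistical design

The study layout is a complete crossing of subjects × conditions
(negative / neutral / positive news exposure before the nap) × angles,
one index value per cell, with body weight as a per-subject covariate.
Because the indices are ordinal or non-normal, the analysis is
rank-based:

* **Friedman omnibus** across the k = 3 conditions within each angle,
  and across the k = 12 angles within each condition. The statistic is
  χ² = 12/(nk(k+1)) Σ Rj² − 3n(k+1) on within-block average ranks.
  The tie-correction factor is **off by default** so that the effect
  size identity W = χ²/(n(k−1)) (Kendall's coefficient of concordance)
  holds exactly for every reported (χ², W) pair; the corrected variant
  is available behind `tie_correction=True`. An all-tied matrix yields
  χ² = 0, not an error. p-values use the χ² approximation with k − 1 df;
  at n = 10, k = 3 with continuous indices the realized null rejection
  rate is ≈ 0.044 at α = 0.05 (slightly conservative, as expected for
  rank-discrete statistics), which is why the calibration suite uses the
  continuous max-change index rather than tied integer counts, whose
  ties make the uncorrected test noticeably more conservative (≈ 0.033).
* **Wilcoxon signed-rank post hocs** on the pairs of each significant
  omnibus, Bonferroni-corrected within that omnibus family (m = 3
  condition pairs or m = 66 angle pairs). Zero differences are dropped;
  tied |differences| get average ranks. The p-value is exact — full 2ⁿ
  enumeration of sign assignments — for n_effective ≤ 12, and a
  tie-corrected, continuity-corrected normal approximation above. The
  effect size is r = |z|/√n_effective with z always taken from the
  normal standardization so r is defined in both regimes. The
  continuity-corrected approximation tracks the exact two-sided p to
  about 0.014 (worst case) at n = 12.
* **Spearman correlations** of body weight against each per-angle index
  within each condition (Pearson on average ranks; t-approximation
  p-value).
* Two-sided p throughout; α = 0.050; effect sizes (W, r, |rho|) are
  attached to significant rows only, mirroring the reporting convention
  of this study design.

## Synthetic sessions and studies

No public recordings exist for this protocol, so the simulator is the
package's test bed. A session is a per-angle **event schedule**: an
initial level drawn uniformly from [20°, 160°], a Poisson-distributed
number of repositioning events (mean 5 per angle per session by
default), event times thinned so every dwell is at least `min_dwell_s`
(4 s = 2 × the default minimum stable duration, guaranteeing
detectability), and level shifts uniform in [20°, 60°]. Session length
is drawn from N(460 s, 50 s) truncated above 60 s — the range such nap
sessions actually span — unless fixed. Observation noise is i.i.d.
Gaussian in angle space (default σ = 1°), making `noise_sigma_deg`
directly comparable to `tolerance_deg`.

Two rendering paths:

* the **fast path** maps schedules straight to angle series for all 12
  angles independently — used by the statistical suites, where session
  counts matter;
* the **geometric path** places the 12 landmarks of a canonical supine
  skeleton (camera overhead, body axis across the frame) so that the 8
  shoulder/elbow/hip/knee angles realize their scheduled values exactly:
  for each triplet the terminal point is rotated about the vertex,
  proximal joints placed before distal ones. Placement happens in pixel
  space and is normalized afterwards, so the realized pixel-space angles
  equal the targets for any aspect ratio. The wrist and ankle angles are
  then *emergent* — both their non-vertex landmarks are already placed —
  and are recorded in the noise-free ground-truth table rather than
  scheduled. An occlusion model drops landmarks in random exponential-
  length gaps.

A **study** is n_subjects (default 10) × 3 conditions of such sessions.
Condition effects enter as multipliers on event rate and shift magnitude
(optionally restricted to a set of angles, e.g. lower limbs); body
weight ~ N(75, 12) kg couples to the event rate as
rate ∝ exp(coupling × weight z-score), with negative coupling emulating
heavier sleepers repositioning less. All multipliers 1 and coupling 0
gives an exchangeable null study. All randomness flows through one
seeded generator hierarchy (`numpy` `SeedSequence` spawning), so studies
are reproducible down to byte-identical landmark streams.

What the generator does **not** emulate: body-pose estimation error
structure (correlated, pose-dependent, heavy-tailed), smooth transitions
during a repositioning (events are instantaneous steps), torso
translation or rotation in bed, blanket occlusion patterns, or any real
sleep physiology. Passing tests therefore demonstrate that the pipeline
recovers the indices its own model class generates — not that the
indices are accurate on arbitrary real video.

## Problem sizes in the verification suites

The recovery suite runs 100 sessions of 200 s at 8 fps (1,200 angle
series; 5 events each, σ = 1°, tolerance 5°, delta 10°) and requires
exact change-count recovery in ≥ 99% of series with stable times within
one frame. The calibration suite runs 500 null studies of 10 subjects ×
3 conditions at the schedule level and requires the per-angle Friedman
rejection fraction on the max-change index to fall in [0.03, 0.07] at
α = 0.05 (measured ≈ 0.04). Oracle suites compare Friedman to a
brute-force rank computation (100 matrices), exact Wilcoxon to full 2ⁿ
enumeration, and Spearman to rank-then-Pearson, all at 1e−9 or exactly.
These sizes are the package's own verification design and run in a
couple of minutes on one core.

## Known limitations

* The triplet table for shoulder, hip, wrist and ankle is a convention;
  results for those angles are not comparable across tools that define
  them differently.
* The movement indices depend on four thresholds with no field-standard
  values; sensitivity to them should be checked on real data.
* The range-based max-change index inflates with session length under
  noise; prefer `max_event_change_deg` when comparing sessions of very
  different lengths.
* Friedman p-values rely on the χ² approximation; at n = 10 with heavily
  tied integer counts the uncorrected test is conservative. Use
  `tie_correction=True` when ties dominate and the W identity is not
  needed.
* MP4 decoding and pose estimation are delegated to pluggable backends;
  the package itself only consumes landmark streams (JSON Lines) or
  pre-computed angle CSVs.
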