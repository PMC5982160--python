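# Methods

## Recognition model

An observation is a sequence of skeleton frames: 20 named joints with 3-D
positions in meters (y up, z toward the sensor, origin at the sensor).
Features are bone directions — unit vectors along the 21 edges of the
skeleton topology (the 19 standard Kinect-v1 edges plus two girdle edges,
SHOULDER_L–SHOULDER_R and HIP_L–HIP_R). The girdle edges are an addition:
without them, a joint set containing shoulders and hips but no trunk joints
(the vB sets) would induce no cross-body reference bone at all.

Bone similarity is `100·(1 − θ/180°)` for the 3-D angle θ between the two
directions of the same bone. This is the simplest monotone map from angle to
percent that is symmetric, bounded in [0, 100], and equals 100 exactly at
θ=0. No per-axis decomposition is used, and rotation about the vertical axis
is **not** normalized away: key samples are assumed recorded facing the
sensor, as the device's usage model implies. Body similarity is the
unweighted arithmetic mean over the template's relevant bones, which gives
the documented influence property: with n relevant bones, changing one bone
similarity by Δ changes the body similarity by exactly Δ/n. Translation of
either skeleton, and any motion of joints outside the relevant set, leave
the score unchanged.

Movement templates are scored frame-synchronously: the trailing window of
the observation (matching the template's duration within a ±20% tolerance)
is resampled to the template's frame count by nearest-frame indexing and the
per-frame body similarities are averaged. Dynamic time warping is
deliberately absent — the protocol requires performing at the template's
speed, and warping would blur the speed constraint the method relies on.
Posture templates are scored on the observation's latest frame.

Prediction: score every registered template; remove each activity whose
score is below its minimum limit of prediction; take the argmax of the rest;
report UNKNOWN if even the winner falls below the global limit (default
50%). Exact ties are broken by template registration order, which makes runs
reproducible when near-ties occur. Limits may be attached to any template,
not only to sink activities; the packaged table only populates the four
sinks.

## Limit calibration

For each sink activity the pre-evaluation yields positives (its template's
scores while truly performed) and negatives (its scores while each bounded
activity is performed). The selection interval is (max(neg), min(pos)) when
those separate ("strict"), else (mean(neg), mean(pos)) ("mean" fallback —
the regime where impostor scores reach into the genuine range), and is
flagged degenerate, never silently resolved, when even the means invert.
The limit is the interval midpoint rounded to 0.1 percentage points;
midpoint because the source material constrains the limit only to lie
inside the interval, and rounding matches the precision at which limits are
tabulated. Per-activity limits are the default; a shared-limit mode selects
one value from the intersection of all intervals and fails loudly when the
intersection is empty (which one activity's outlying interval typically
causes).

## Synthetic motion generator

The generator stands in for unavailable human recordings. Each of the eight
activities is a deterministic script in joint-angle space — a function of
body proportions and phase p∈[0,1] — rendered by forward kinematics, so
bone directions are independent of body size. Per participant, segment
lengths are drawn uniformly from anthropometric ranges (upper arm
0.25–0.32 m, forearm 0.22–0.28 m, thigh 0.38–0.46 m, shank 0.36–0.44 m,
trunk segments 0.22–0.28 m, etc.), left/right symmetric.

Scripts (duration 2 s each, 30 fps; postures static, movements end at an
activity-characteristic pose rather than the neutral stance, since decisions
happen while the motion is in progress and a window ending at rest would
trivially resemble Stand):

* **Stand** — neutral stance.
* **Stay Seated** — hips and knees at 90°, pelvis lowered to shank height.
* **Walk [D]** — sinusoidal contralateral arm/leg swing (hip ±30°, swing
  knee flexion 50°, arm ±25°, 1.75 cycles) with the pelvis drifting toward
  the sensor.
* **Walk Backwards [D]** — the time-reversed gait (knee flexion now
  accompanies the backward swing), pelvis drifting away.
* **Drink [D]** — right elbow flexion to 140° with slight shoulder raise,
  bringing the wrist toward the head.
* **Grab Object [D]** — straight right-arm forward reach to 60° shoulder
  flexion.
* **Leg Flexion [I]** — left knee flexion to 100° with an 18° compensatory
  forward trunk lean.
* **Leg Circular Swing [I]** — the extended left leg traces three quarters
  of a 25° circle in the sagittal–frontal plane, 14° trunk lean.

[I] variants of right-sided scripts (and vice versa) are exact frame-level
mirrors; the left/right mirror of a frame reflects x about HIP_CENTER and
swaps L/R labels, an involution that preserves all inter-joint distances.

The noise model has four components, all seeded per
(participant, activity, repetition):

* **Jitter** — Gaussian position noise, base sd 0.01 m per axis, scaled per
  joint by a reliability weight (trunk/head 0.4, shoulders/hips 0.7,
  elbows/knees 1.0, wrists/ankles 1.3, hands/feet 1.6): the trunk moves
  little and is never occluded, distal joints are tracked worst.
* **Spikes** — rare large errors (sd 0.10 m) modelling occluded-joint
  inference, base probability 0.02 per joint per frame, scaled by the same
  reliability weight **and** by the joint's speed relative to the pelvis
  (zero for static joints, saturating at 2× at 0.5 m/s). A still user never
  triggers the inference failure mode; joints in fast motion trigger it
  most.
* **Execution variability** — one multiplicative draw N(1, 0.10) per
  repetition applied to all script joint angles: a person reproduces the key
  sample's speed but not its exact amplitudes.
* **Balance sway** — during one-legged activities only, the right arm
  performs an unconscious forward reach with the same arc shape as the Grab
  Object script, peak displacement 0.55 m (≈56–63° of shoulder flexion
  depending on arm length). This is the mechanistic realization of the
  confusion hypothesis: the sway is invisible to the leg activity's own
  template (arms are irrelevant joints) but closely matches the Grab Object
  template, while the trunk lean that accompanies one-legged balance is
  visible to trunk-including variants — so vT can separate what vB cannot.

What the generator does **not** emulate: biomechanically validated gait,
inter-joint noise correlation from the tracker's skeleton fitting, occlusion
geometry (speed is used as a proxy), view-angle changes, or the real
volunteers' anthropometrics and idiosyncrasies. Passing tests therefore
demonstrate the algorithmic properties (gating, variant behavior,
calibration soundness) and the qualitative direction of the strategy
comparison under these controlled conditions — not human-subject accuracy
percentages, which are out of reach without the original recordings.

## Evaluation harness

A protocol run performs, for each (participant, activity, repetition), one
generated repetition, classified under every configured joint-set variant
against that participant's own zero-noise key samples (the personalised
single-exemplar usage). Bookkeeping: **Suc** counts correct predictions,
**Vic** counts repetitions where a variant scored the true activity
strictly above every other variant (exact ties award nothing, so Vic totals
may be below the trial count), **Rate** = 100·Suc/repetitions. Strategy
arms (variants-only, limits-only on the vB sets, combined) are evaluated on
identical seeded trials, so arm differences are strategy differences, not
sampling noise. Confusion matrices include UNKNOWN as a prediction label.

Problem sizes: the full protocol is 5 participants × 8 activities × 25
repetitions (1000 trials), used by `scripts/acceptance.py`; the test suite
uses 2–5 participants and 2–10 repetitions per cell, which already gives
stable qualitative behavior at a few seconds per run.

## Numerical choices

* Degenerate bones (endpoints within 1e-6 m) are errors, not zeros.
* Similarities are kept at full float precision internally; rounding to
  0.01 points happens only in CLI/report output. Self-similarity is exact
  to ~1e-6 of a percent (the arccos limit at unit dot products), which is
  why identity assertions use 1e-5 tolerances.
* Nearest-frame resampling indices are `round(linspace(0, n−1, m))`; a
  window holding each template pose at double fps reproduces the template
  score exactly.
* fps is stored redundantly in sequence files and checked against frame
  spacing within 1%.
* The execution-scale draw is clipped to [0.5, 1.5] to keep poses physical.

## Known limitations

* Scoring is frame-synchronous from the repetition's start; there is no
  key-frame progression model or phase search, so observations must be
  phase-aligned with templates (the harness guarantees this; live use would
  need a sliding decision cadence, which `predict` supports per incoming
  frame via trailing windows).
* The single 3-D angle per bone is one concrete choice among angle
  decompositions with the same invariants; alternatives (two planar angles)
  would change absolute percentages but not the documented properties.
* Whether vB should include only the active side's girdle is ambiguous in
  the source material; both shoulders and both hips are included here.
* Calibrated limits from the synthetic pre-evaluation are higher than the
  packaged defaults because the synthetic impostor distributions are
  tighter than human ones; the packaged table is kept as the reference
  default.
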