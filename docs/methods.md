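# Methods

## The measurement model

The behavioral depression degree (BDD) treats depressive severity as a loss
of *diversity* in observable behavior.  Two per-frame streams from a
perception front end — a 7-class facial-expression probability vector and an
18-keypoint body pose — are condensed per session into Shannon entropies H
(expression) and G (action), mixed by a convex weight λ into the behavioral
entropy F = λH + (1−λ)G, and reported as B = 1 − F.  The underlying
assumptions, in the package's terms:

* flatter affect ⇒ the session-aggregate expression distribution
  concentrates on one class ⇒ H falls;
* reduced movement range ⇒ displacement concentrates in few joints (or
  vanishes) ⇒ G falls;
* both effects track the same latent severity, so a single convex mixture
  correlates with clinical scale totals, and one mixing weight λ serves an
  entire cohort.

### Normalization and units

The entropy definitions leave the logarithm base free, but mixing a 7-class
entropy with an 18-category entropy linearly only yields a score-like
B ∈ [0, 1] if both entropies share a scale.  Each entropy is therefore
normalized by the log of its category count (log 7, log 18), making H and G
dimensionless in [0, 1] and λ a true convex weight.  `normalized=False`
gives nats for either entropy.  The convention 0·log 0 = 0 applies
throughout, and a completely static subject (D_z = 0) gets G = 0: no
movement is read as minimal action diversity, not as undefined.

Keypoint coordinates are normalized per axis to the unit square, so motion
amplitudes are unitless fractions of the image extent; per-joint mean
amplitudes of order 10⁻²–10⁻³ are typical for a seated subject.

### Aggregation choices

* **H**: the default computes one entropy of the mean per-frame
  distribution.  The alternative — mean of per-frame entropies
  (`aggregation="per_frame_mean"`) — is systematically lower (Jensen) and is
  exposed because the two answer slightly different questions: diversity of
  the session's overall affect vs. average within-frame uncertainty.
* **D(yⱼ)**: mean (not sum) displacement over frame pairs (t, t + stride),
  so sessions of different lengths are comparable, and only pairs where the
  joint is detected in both frames count.  Joints never co-detected in a
  pair get D = 0 with pair count 0 — undetected joints are never
  interpolated.  The frame stride is configurable (default 1) because the
  effective sampling rate fed to the displacement computation is a free
  choice of the front end; for uniform motion D scales linearly with
  stride.

### λ fitting

`fit_lambda` scans λ over an inclusive grid (default step 0.01), computes
B for every (patient, session) point, the sample Pearson r of B against
each of SDS, SAS and HAMD pooled over all points, and the mean of the three
r values; the reported λ maximizes that mean, with exact ties broken toward
the larger λ for determinism.  Correlations are signed — the score is built
so that B co-moves positively with severity — and "similarity" is r
expressed as a percentage.  Pooling across the cohort (rather than
averaging per-patient correlations) is the default because one λ is fitted
for everyone; `per_patient=True` averages within-patient correlations as a
sensitivity analysis.  Pearson's affine invariance means raw scale totals
are compared without standardization.

## Clinical scales

SDS and SAS are 20-item self-ratings, items scored 1–4.  The published
severity cut-offs (50/60/70) apply to the *index* score ⌊1.25 × raw sum⌋,
so item-level scoring defaults to index mode with raw mode available.
Severity bands are implemented as half-open ranges so they are contiguous
over real-valued totals while reproducing the printed integer cut-offs
exactly.  The HAMD bands in common clinical use leave totals of 8–17
between "no depression" (< 8) and "mild or moderate" (18–35); this package
maps 8–17 to "mild", which matches how totals in that range are described
clinically.  Percent changes are 100 × (baseline − end)/baseline rounded
half-up to one decimal, so a positive value is an improvement.

## The synthetic cohort generator

The generator exists so that the entropy computations, the λ fit, and the
reporting chain can be exercised end to end with known ground truth.  One
latent severity s ∈ [0, 1] per (patient, session) drives:

* **Expression frames** — Dirichlet(κ·target + 0.05) draws around a target
  distribution interpolating uniform (s = 0) → sad-dominant (s = 1), so
  frames are valid distributions by construction and expected H falls with
  s.  Default κ = 80 puts realistic frame-to-frame wobble around the
  target.
* **Pose frames** — mean-reverting random walks of the 18 joints around a
  standing-figure anchor, clipped to the unit square.  The per-step scale
  is α(1 − s)·exp(−kⱼ·s) plus a head-only floor: distal joints (legs
  kⱼ = 5, arms kⱼ = 3) freeze faster than the head region (kⱼ = 0.8), and a
  residual head fidget (floor 0.003) persists at high severity.  Both total
  motion D_z and action entropy G therefore fall as s rises; at s = 1 with
  zero floor the subject is perfectly static and G = 0.  A configurable
  per-joint dropout (default 2 %) emulates detection failures.
* **Scale totals** — three *distinct* increasing affine maps of the
  session's latent B\* plus Gaussian noise (default sd 2 points), clipped
  to each instrument's range.  Crucially, B\* is computed from the H and G
  the features module actually measures on the generated tracks, so with
  zero noise every scale is exactly affine in B\* and the grid scan must
  recover the generating λ\* at grid resolution with mean similarity 1.
  Totals are kept real-valued rather than rounded so this exactness holds.

Severity trajectories are per-patient monotone declines: a starting
severity drawn from (0.5, 0.95) relaxing linearly by a fraction drawn from
(0.3, 0.6) over the sessions — a cohort that is moderately-to-severely
depressed at intake and broadly improves under treatment.

Two small design points deserve explanation:

* **Modality jitter.**  The severity seen by the expression stream and by
  the pose stream is s plus independent Gaussian jitter (sd 0.06, clipped
  to [0, 1]).  Faces and bodies do not track the underlying state
  identically from session to session, and this decoupling is also what
  makes λ statistically identifiable: with H and G driven by exactly the
  same scalar they are nearly collinear across the cohort and the Pearson
  objective is almost flat in λ.  At the default jitter the fitted λ lands
  within 0.05 of the generating 0.94 for the default cohort size (40 × 7
  sessions, 200 frames each) while the severity → H and severity → G links
  remain strongly monotone (rank correlations below −0.9 on noiseless
  cohorts).
* **Calibration.**  The affine scale maps and trajectory ranges were chosen
  once so that cohort-level BDD averages sit near the low-0.3s to 0.4
  region typical of treated outpatient cohorts.  The simulated treatment
  effect is steeper than most real cohorts show (mean BDD roughly 0.51 at
  intake to 0.17 at session 7); widening or flattening the trajectories is
  a one-line `CohortSpec` change but weakens λ identifiability by
  restricting the severity range, so the defaults favor a well-posed
  recovery experiment over demographic realism.

### What passing tests do and do not show

The generator emulates the *statistical structure* the metric relies on —
monotone severity→entropy links, a shared latent driver, noisy affine scale
responses — not real video.  Passing tests demonstrate that the entropy
math, missing-data rules, fitting procedure and reporting chain are correct
and that λ recovery is well-posed under that structure.  They say nothing
about perception accuracy on real faces and bodies, about whether clinical
populations actually satisfy the monotone-link assumptions, or about the
affine form of the scale response; those are empirical questions requiring
recorded cohorts.

## Perception contracts

Real face detection, expression classification and pose estimation are
pluggable: any object with `classify` (valid 7-vector, sum 1 ± 1e-6) and
`estimate_pose` (18 joints; undetected joints flagged absent, never
invented) satisfies the backend contract.  The package pins the expression
CNN only as a shape specification — eight convolution blocks from 48×48×64
down to 3×3×512 and a dropout/FC/softmax head emitting 1×1×7 — sufficient
to sanity-check a loaded weight file; kernel sizes, strides and the dropout
rate are deliberately unconstrained.  A deterministic mock backend
(severity-profile-parameterized, bit-reproducible per seed) stands in for
trained weights in tests and demos.  When several faces are detected in a
frame, the highest-confidence box is kept (single-subject recording
assumption); frames with no detected face contribute nothing and are
logged, not interpolated.

## Numerical conventions

* Entropy inputs are validated to sum to 1 within 1e-6; stream readers
  renormalize rows off by ≤ 1e-2 (serialized softmax output commonly drifts
  at low precision) and reject anything worse, with the row number.
* Pose coordinates outside [0, 1] by ≤ 0.01 are clipped with a warning;
  worse values are rejected.
* Pearson correlation on a constant series raises an error rather than
  returning 0 — an undefined correlation silently treated as "no
  correlation" would bias the λ scan.
* Floats are serialized with 9 significant digits, making
  write → read → write cycles byte-stable; the BDD reader rebuilds
  B = 1 − F after a 1e-8 consistency check since independently rounded F
  and B can disagree at the last digit.
* All randomness flows through seeded NumPy generators; identical seeds
  give bit-identical cohorts and mock-backend outputs.

## Problem sizes

Default cohorts are 40 patients × 7 sessions × 200 frames per stream —
large enough for the λ-recovery experiment to be well-posed, small enough
that the full test suite and the acceptance script each run in seconds.
Longer sessions sharpen the per-session entropy estimates
(frame-sampling noise in H and G shrinks roughly as 1/√frames) but do not
change any qualitative behavior.

## Known limitations

* λ is fitted by grid search with a point estimate only; no confidence
  interval or cross-validation is provided.
* The severity bands and index-mode assumption for SDS/SAS follow the
  standard published cut-offs; instruments scored differently need their
  totals supplied directly.
* Expression aggregation ignores temporal ordering within a session
  (micro-expression timing, affect dynamics are out of scope).
* No smoothing or imputation of keypoint trajectories: detection dropouts
  simply reduce the pair counts.
* The perception layer is a contract; nothing here validates an actual
  detector or pose estimator beyond output-shape checks.
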