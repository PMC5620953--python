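# Methods

`actitag` turns a tri-axial acceleration stream from a single lower-back
(L5) sensor into a fine-grained actigraphy: one of ten activity tags —
sit, stand, lie, walk, and the six postural transitions between sit, stand
and lie — per 3-second window. This note documents the model, the choices
that were genuinely open, and what the synthetic test bed does and does
not demonstrate.

## Signal model and preprocessing

The raw signal is acceleration in g at 100 Hz. Sensor bias and scale are
estimated from nine static postures by nonlinear least squares
(Levenberg–Marquardt through `scipy.optimize.least_squares`), minimizing
the deviation of each static mean from unit gravity norm. A kernel-3
median filter removes single-sample artifacts (replicate-padded ends, via
`scipy.ndimage.median_filter`). Body acceleration is the residual after
subtracting a 1 Hz low-pass estimate of gravity; a 0.5–15 Hz band-pass
copy is kept for the orientation variant. All filters are 4th-order
Butterworth applied forward–backward (`sosfiltfilt`): the named cutoffs
say nothing about phase, and zero-phase filtering avoids shifting
transition onsets relative to their window labels.

Orientation per sample, in degrees:

    roll  = atan2(a_x, sign(a_z)·a_z + 0.01·a_x²)
    pitch = atan2(−a_x, sqrt(a_y² + a_z²))
    tilt  = atan(a_z / ‖a‖)

with `sign(0) = +1`; the `0.01·a_x²` term keeps the roll denominator away
from zero. The two-argument (quadrant-aware) arctangent is used for roll
and pitch, the single-argument form for tilt. A zero-magnitude sample
yields tilt 0 and a log message. **Open choice:** computing orientation
from the band-passed signal removes DC and therefore destroys the static
posture reading, which is exactly what separates sit/stand/lie. Default:
orientation from the calibrated-denoised signal; the literal
band-pass-first variant is available as `orientation_source="bandpassed"`.

Windows are 3 s with 1 s overlap (2 s hop); trailing partial windows are
dropped because the descriptors assume full 3-s support.

## Descriptors

98 per window: for each of six channels (3 body-acceleration axes, 3
orientation angles) — mean, variance, RMS, number of peaks, max–min peak
difference, number of troughs, mean peak↔trough gap, zero crossings,
coefficient of variation, IQR, histogram entropy, power, dominant
frequency, power in a ±0.5 Hz band around it; per signal type — the three
lag-0 Pearson axis correlations and mean/variance of the signal magnitude
area (across 1-s thirds) and of the per-sample magnitude vector. Peaks
and troughs use a prominence threshold of 0.05 channel units; entropy is
Shannon entropy in bits of a 16-bin histogram; the coefficient of
variation guards `|mean| < 1e-9` with 0. None of these conventions is
fixed by the descriptor list itself; they are stated here because they
affect reproduction.

## Feature selection

Per classifier node, classic SFFS: conditional inclusion of the
best-improving descriptor, then conditional exclusions while they improve
the criterion, stopping at `max_features` (default 5) or no improvement.
The criterion is stratified 3-fold CV accuracy. By default the criterion
classifier is a fast vectorized Gaussian naive Bayes over a pool
prefiltered to the top 30 descriptors by univariate F statistic; a
wrapper around the node's own forest is exorbitant inside
leave-one-subject-out × 8 nodes, and on the problems tested the NB
wrapper recovers the same informative descriptors (the SFFS oracle test
checks equality with exhaustive search). Any sklearn estimator or a
custom criterion callable can be substituted. Ties break toward the
lowest descriptor index; the start descriptor is drawn from the seed.

## Subspace mappings

Selected descriptors are z-scored with training-fold statistics, then
mapped to d = min(10, n_selected − 1) dimensions (the hierarchy level
never states a target dimension; this keeps nodes with few descriptors
full-rank).

**MCM** learns a rank-d Mahalanobis factor A (Σ = AᵀA) minimizing
Σᵢ KL(p0(·|i) ‖ p̂(·|i)), where p0 is the row-normalized same-class
indicator and p̂(j|i) ∝ exp(−d_ij) with d_ij the mapped squared distance.
Σ is *learned*, not the data covariance — the only reading under which
"collapsing" classes is an optimization at all. Gradient descent with
backtracking line search (objective provably non-increasing), A
initialized from a seeded Gaussian scaled by 1/√m, stopping at relative
decrease < 1e-5 or 60 iterations. The pairwise objective is O(n²), so
node fits subsample to 250 seeded rows; with tags pooled into 2–3 groups
per node this retains class balance in practice.

**DAUT** is the all-linear discriminative autoencoder
min ‖X − W1HX‖² + λ‖Y − W2HX‖² with one-hot Y. All three blocks have
closed-form normal-equation updates, so it is solved by exact alternating
least squares rather than gradient steps on H — same stationary points,
monotone objective, no step-size tuning. H is initialized from the top-d
right singular subspace of X (deterministic; at λ = 0 this is already the
Eckart–Young optimum). A 1e-8 ridge guards rank-deficient Gram matrices.
λ defaults to 1.0 inside the forest; `lam="lcurve"` picks the
maximum-curvature corner of (log reconstruction error, log classification
error) over a 25-point grid in [1e-4, 1e4].

## The dichotomy

Eight nodes, ten leaves, five levels; see the `dmf` module docstring for
the full tree. The grouping runs from the coarsest contrast (active
vs. static) down to sibling transitions, so most of the training data is
used where classes are easiest to tell apart, and the rare transition
windows only compete against each other. Each node trains a 100-tree
random forest (max depth 12, bagging fraction 0.8) on its mapped data with
`class_weight="balanced_subsample"`, which reweights each bootstrap — the
practical answer to static bouts outnumbering transitions by an order of
magnitude. Node confidence is the fraction of tree votes for the chosen
group.

Fused confidence multiplies per-level terms along the routed path;
weighted fusion multiplies ϕ_k·p_k with ϕ_k = 2(l−k+1)/(l²+l), l = 5, so
decisions near the root dominate. The weights are *not* renormalized over
the visited levels: the printed rule has no such renormalization, and the
consequence — absolute fused confidences are small and depend on path
depth — is harmless because the confidence bound δ is calibrated on the
same scale.

## Logic filter

The ten tags form a feasibility automaton Θ: every tag may follow itself;
a posture may be followed by its departing transitions; a transition by
its destination posture and that posture's departures; walking connects
directly with stand in both directions (no transition tag exists for
walk↔stand). Θ ships as a documented constant with a CSV override.

δ is the ROC operating point of (fused confidence → prediction correct)
nearest the ideal corner (0, 1), calibrated on a stratified 15% split of
each fold's training windows (held out of all model fitting). A
prediction is examined only if its confidence is below δ *and* it differs
from the previously retained tag; it survives iff some retained tag in
the previous `order` steps validly precedes the last retained tag, and
the last retained tag validly precedes it. Otherwise the previous
retained label is carried forward. Default order 2. The ∃-reading of the
history check is used (a valid sequence *found* among the last `order`
predecessors), and the correction applies to the current low-confidence
label; the variant indexing the correction one step back is kept behind
`literal_indexing=True`. With no history at all the predecessor check is
vacuously true — the first retained label cannot be invalidated.

## Synthetic cohort

The generator emulates the activity-circuit study design: 10 patients +
20 controls by default, each performing a duration-jittered circuit
(walk, repeated sit/stand stations, lying stations, ~75 s, ≈ 40 windows
per subject). The signal model is a single orientation angle in the
device x–z plane driving a rotated unit gravity vector (stand 0°, sit
20°, lie 90°), plus tag-specific kernels: a 0.30 g step-frequency
sinusoid with harmonics for walking, an angular-velocity bump for
transitions, and white noise (σ ≈ 0.02 g). Patient impairments scale
with a severity drawn uniformly in (0.2, 1] (a moderate-to-severe
cohort): tremor at 4–6 Hz with amplitude 0.15 g × severity, transitions
stretched by 1 + severity with a 0.3 × severity chance of a mid-movement
pause, a hunched baseline tilt of 10° × severity, and a slightly slower
step frequency. These magnitudes are one-time choices — no quantitative
description of the patient signals exists to fit them to.

What passing tests show: the pipeline separates ten classes far above
chance on gravity-plus-kernel signals, the filter removes infeasible
low-confidence errors, and patient/healthy mixing behaves directionally
as expected. What they do not show: performance on real RA recordings,
whose within-class heterogeneity (unorthodox resting postures, composite
lying-to-stand strategies, genuine gait dynamics) the generator does not
attempt to reproduce.

## Problem sizes and numerics

The shipped evaluation runs LOSO over the 30-subject synthetic cohort
(~1200 windows, 30 folds) plus the patient-fold training-setting
comparison; this completes in a few minutes on one core and is the size
at which all distributional claims in the test suite are made. Degenerate
cases: a calibration split in which the model is entirely right (or
wrong) disables the filter for that fold (δ = 0) with a warning; SFFS
clamps its CV fold count to the smallest class; constant descriptors get
variance floors rather than NaNs. All randomness flows through
`numpy.random.SeedSequence` spawns of the user seed — same seed, byte
identical outputs, independent of node execution order.

## Known limitations

* The synthetic generator is not biomechanical; results on it bound
  nothing about clinical accuracy.
* Orientation is accelerometer-only and meaningful only up to the
  gravity direction (no yaw); the tilt formula saturates at ±45°
  for unit-norm input by construction.
* MCM subsampling (250 rows/node) trades objective fidelity for runtime;
  raise `DMFConfig.mcm_max_samples` for offline fits.
* The logic filter corrects forward only; an infeasible *confident*
  prediction is never revisited.
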