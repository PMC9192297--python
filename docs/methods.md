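# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Problem setting

Epoch-level seizure detection on multichannel scalp EEG in the CHB-MIT
regime: 256 Hz sampling, 16-bit storage, the 18 bipolar channels of the
longitudinal 10-20 montage shared by all patients, and a 2 s analysis
window.  The design premise is that denoising is *not* required:
artifact-heavy epochs are not cleaned but routed to their own
classifier, so that each classifier sees a more homogeneous input
distribution.

## Riemannian potato

Each epoch's channel covariance is estimated from the row-demeaned data
and shrunk toward a scaled identity, `(1−λ)C + λ(trC/n)I` with
λ = 1e−3 by default.  The shrinkage guards a 10×10 estimate from
512 samples against near-singularity (duplicated or linearly dependent
channels) while perturbing geodesic distances negligibly; λ is exposed
for callers with other channel counts.

Distances use the affine-invariant metric
δ(A,B) = √(Σ log²λᵢ(A⁻¹B)), computed via the generalized symmetric
eigenproblem rather than explicit matrix square roots.  The metric is
congruence-invariant, so the gate is unaffected by channel scaling or
any fixed linear remixing of the montage.

The reference point is the Fréchet mean, computed by the tangent-space
fixed-point iteration initialized at the arithmetic mean.  The plain
unit-step iteration converges only linearly when the set contains far
outliers (20× artifacts sit at geodesic distance ~ √n·log 400 from the
bulk), so the step is damped adaptively: halved when the tangent-norm
residual grows, allowed to recover (×1.2, capped at 1) when it shrinks.
`riemann_mean` defaults to tol 1e−8 on the tangent Frobenius norm and
50 iterations (returning the best iterate with a warning on
non-convergence); the potato fit requests up to 250 iterations, enough
for the ~0.83 linear rate observed on contaminated records.

The potato itself is an iterative trimmed fit: compute the mean and the
mean/sd of log-distances on current inliers, flag z > z_threshold
(default 2.5), refit on the survivors, stop when the inlier set is
stable (≤10 rounds).  Conventions: the z-score of a zero distance is
floored at −10; a point exactly at the threshold is *normal* (strict
inequality, deterministic boundary); if the log-distance spread
collapses below 1e−12 (all covariances essentially identical) nothing
is flagged, since identical covariances carry no outlier evidence; a
fit in which every epoch would be flagged raises.

The potato is fit per record on **all** epochs jointly, unsupervised.
Fitting it per class would leak labels at inference time; the
class-split variant remains available by simply filtering epochs before
`fit_potato` (as `scripts/reproduce_chbmit.py` users may do for
exploratory significance tables).

## Features

* **Welch PSD** — rectangular window, M = 256 samples (1 s) per segment,
  50% overlap, hence L = 3 averaged periodograms per 2 s epoch; segments
  are mean-removed (DC leakage under the rectangular window).  The
  rectangular window's normalization factor U = (1/M)Σd²(n) equals 1 and
  is recorded in the returned `Spectrum`.  One-sided density scaling, so
  Σ power·Δf approximates the signal variance.  The per-channel feature
  is the arithmetic mean of the PSD over 0.5–100 Hz — the stated
  physiological range of the recordings, excluding DC.  M and the
  overlap are conventions of this package (1 s segments give 1 Hz
  resolution); both are configurable.
* **Sample entropy** — m = 2, r = 0.2·sd, Chebyshev distance,
  self-matches excluded (the Richman–Moorman convention), counting the
  N−m templates that admit an (m+1)-extension.  −ln(A/B); A = 0 returns
  +inf, B = 0 raises.  A zero-variance epoch falls back to an absolute
  tolerance of 1e−12 so constants return 0 instead of erroring.  The
  implementation computes Chebyshev template distances as running
  maxima of the scalar distance matrix along diagonal offsets — exact
  integer pair counts, verified bit-for-bit against an O(N²m) loop
  oracle in the tests.

## Channel selection

The nine-region map pairs each lateral chain channel with its medial
neighbor; the central region is (FZCZ, CZPZ) and always contributes
both channels (closest to deep sources, least noise, but mutually
weakly correlated in the non-seizure condition).  For the other eight
regions the rule is:

1. **Dominance**: a channel wins iff its record-averaged mean PSD is
   larger in *both* conditions (seizure and non-seizure) and its
   relative excess is ≥ 10% in at least one.  The 10% margin is this
   package's codification of "clearly larger": on the shipped summary
   tables it reproduces every dominant pick (T8P8, FP1F3, FP2F4, T7P7)
   and every uncertain call (F7T7/F3C3, P7O1/P3O1, F4C4/F8T8,
   P4O2/P8O2).  The margin is a config parameter.
2. **Coverage**: uncertain regions are resolved after all dominant
   regions, in montage order, by picking the candidate whose minimum
   Euclidean scalp distance to everything already selected is largest.
   Positions are schematic 2-D 10-20 coordinates — outer-ring
   electrodes on the unit circle at the standard 36°/72° spacing, the
   inner grid at ±0.5 — with a bipolar channel placed at the midpoint
   of its electrode pair.  Ties break by montage order.

On the shipped tables this yields
F7T7, T7P7, FP1F3, P3O1, FP2F4, P4O2, F8T8, T8P8, FZCZ, CZPZ, which
also ships as `SELECTED_CHANNELS_10` for users who do not recompute the
tables.  Note P4O2/P8O2 is *uncertain* under the dominance rule (P8O2
is slightly larger in the seizure condition) and resolves to P4O2 by
coverage, since P8O2 sits next to the already-selected T8P8.

## Significance machinery

All group comparisons use classical one-way ANOVA (two-group
comparisons included, where F = t² exactly), p from the F distribution
on (k−1, N−k) df.  No multiple-testing correction is applied; results
are reported per channel and per feature.  Degenerate input (zero
within- and between-group variance) returns F = 0, p = 1.

## Detection and fusion

Detectors are seeded random forests (500 trees; probability = fraction
of trees voting seizure).  Per-partition configurations: normal —
mtry 2, thresholds (0.5, 0.55); abnormal — mtry 1, (0.4, 0.6); original
(undivided data) — mtry 2, (0.5, 0.5).  The dual threshold labels an
epoch seizure iff p ≥ t_epilepsy and non-seizure iff
1−p ≥ t_nonepilepsy; an epoch in the gap between the two is assigned
non-seizure, the clinically conservative choice toward false alarms.
(Consequently the decision reduces to p ≥ t_epilepsy; both thresholds
are kept in the configuration for fidelity to the stated operating
points.)  Class imbalance is handled only through these thresholds — no
resampling.

Evaluation is stratified k-fold cross-validation at epoch level
(k = 5, reduced automatically when a class has fewer epochs than
folds), with an optional leave-one-record-out mode.  Within each fold
every detector trains on the training rows of its partition and
predicts its partition's test rows; decisions are pooled over folds.
The fused result pools the normal and abnormal detectors' decisions
over the union of their epochs.  A partition with fewer than two
classes in training is skipped with a warning; the fused result then
degenerates to the remaining partition.  One pipeline seed drives the
potato, fold shuffling and tree bootstraps.

## Synthetic generator

The generator produces the regime the method assumes, not
physiological EEG:

* background: per-channel Gaussian noise shaped to a 1/f power
  spectrum (flat below 0.5 Hz), linearly mixed with nearest neighbors
  at a configurable level (default 0.5) and rescaled to 50 µV RMS —
  reproducing the spectral slope and the inter-channel redundancy the
  channel-selection stage relies on;
* seizures: a sinusoid near 3 Hz plus a weak second harmonic at
  ictal_gain (default 4) × background RMS, confined to the configured
  intervals — elevated narrowband power and low complexity, the two
  feature directions of real ictal EEG;
* artifacts: per-epoch Bernoulli events (rate in epochs per 100) that
  add a half-second boxcar noise burst plus a baseline jump at
  artifact_gain (default 20) × background RMS on a random channel
  subset — covariance outliers that do not encode the potato's own
  statistic.

Ground-truth masks label an epoch ictal only when fully inside a
seizure interval (boundary epochs are non-seizure — unambiguous masks
for testing).  Not emulated: seizure morphology and evolution,
eye-blink/EMG-specific artifact signatures, inter-patient variability,
non-stationary background.  Passing tests therefore demonstrate the
*mechanics* (gating, features, routing, fusion) under controlled
conditions, not clinical performance.

## Problem sizes used by the tests

The artifact-recovery fixture is 1000 s (500 epochs, 5% artifact rate,
20× gain, seed 1); the end-to-end fixture is 400 s with one 60 s
seizure (4× ictal gain, 5% artifacts, seed 1), and the fusion-vs-
baseline comparison repeats it over seeds 0–19.  These sizes give
stable statistics (≈25 artifact epochs, 30 ictal epochs per run) while
keeping a full test run on a single CPU short.

## Known limitations

* EDF support is plain EDF (hand-rolled 16-bit writer, 1 s records,
  symmetric physical range; reading via MNE); EDF+ event streams and
  BDF are out of scope, and non-integer sampling rates cannot be
  written.
* The potato assumes one dominant clean mode per record; recordings
  that are mostly artifact (or contain long state changes) violate the
  trimmed-fit assumption.
* Headline clinical metrics depend on the CHB-MIT corpus and a chosen
  potato threshold; the repository reproduces procedures and
  synthetic-data properties, and `scripts/reproduce_chbmit.py`
  documents the corpus-scale run without being exercised in CI.
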