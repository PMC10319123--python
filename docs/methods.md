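# Methods

`fixcca` implements a between-subject correlated-component analysis of
fixation-related potentials (FRPs): spatial filters are extracted that
maximize the correlation of fixation-locked EEG across a reference group of
participants, each participant is scored for how congruent their own
fixation-locked activity is with that group, and the per-component scores
are aggregated into group-discrimination metrics. The intended application
is continuous naturalistic reading tasks (serial naming of a letter matrix
under four conditions crossing modality and confusability), where no
experimenter-controlled trial structure exists and eye-fixation onsets serve
as the time-locking events.

## Signal model and the component decomposition

For participant *s* and one task condition, the single-trial FRPs are the
EEG epochs in the half-open window [−200, +500) ms around each fixation
onset, baseline-corrected by the per-channel mean of [−200, 0) ms. The
epochs (truncated to the group-wide common count F, earliest first) are
horizontally concatenated into `X_s ∈ R^{D×TF}` (D channels, T samples per
epoch).

Pairwise cross-covariances are `R_ij = X_i X_j' / K` with K the column
count. Over a reference group S of size S:

    R_b = 1/(S(S−1)) Σ_{i≠j} R_ij        (between-subject)
    R_w = 1/S Σ_i R_ii                   (within-subject)

For a spatial filter **w**, ρ(**w**) = (**w**'R_b **w**)/(**w**'R_w **w**)
is the average between-subject correlation of the projected data. Its
stationary points solve the generalized eigenvalue problem
`R_w⁻¹ R_b w_k = λ_k w_k`; components are kept in descending λ order, and
ρ(w_k) = λ_k exactly. Numerically the pencil is solved by symmetric
whitening: `R_b` is symmetrized, `R_w` is shrunk (below), and
`eigh(R_w^{-1/2} R_b R_w^{-1/2})` guarantees real eigenvalues. Filters are
unit-norm with the sign fixed so the largest-magnitude entry of the forward
model is positive.

The forward model (scalp topography) of component k is
`a_k = R_w w_k / (w_k' R_w w_k)`; temporal profiles are grand averages of
`w_k' sFRP(t)` per group.

### Shrinkage

Average-referenced EEG is rank-deficient (the constant channel direction is
an exact null space), so `R_w` is shrunk toward the scaled identity:
`R_w ← (1−γ) R_w + γ (tr R_w / D) I`, default γ = 0.05 (configurable). The
same scaled-identity regularization is applied to the within-subject
denominator when scoring participants, for the same reason; with γ = 0 the
score is the exact covariance ratio.

## Congruency scores and leave-one-out extraction

Participant *s* is scored against a reference group on component k by

    score_{s,k} = (w_k' R_sb w_k) / (w_k' R_sw w_k),
    R_sb = 1/S Σ_i (R_si + R_is),   R_sw = 1/S Σ_i (R_ss + R_ii).

A participant identical to every reference member scores exactly 1; an
independent participant scores → 0 as data grows; a sign-flipped source
scores negative. (The between/within construction of the denominator
mirrors ρ; a literal reading of the score with the numerator repeated in
the denominator would be identically 1 and carries no information.)

Component extraction is leave-one-out: a reference-group member is scored
on components extracted from the other S−1 members, so their own data never
touches the basis used to score them.

**Reference-size matching.** Participants outside the reference group are
*also* scored against S−1 members, dropping one member in deterministic
rotation. Scoring members against S−1 references but non-members against S
creates a systematic, group-coded difference in the features (different
basis-estimation noise and pooling) that a downstream classifier exploits
even when the two groups are statistically identical — at small cohort
sizes this alone drove cross-validated "discrimination" of null cohorts to
AUC ≈ 1. Matching the reference size for every scored participant removes
the artifact; it is the standard fair-comparison device when scoring
out-of-group individuals against a normative cohort.

## Group metrics

* **Cumulative metric**: the sum of the top K̂ = 3 scores (the knee of the
  eigenvalue spectrum; configurable).
* **LASSO-weighted metric**: an L1-regularized logistic regression over the
  top K = 10 scores, evaluated leave-one-participant-out. Features are
  z-scored with training-fold statistics; the penalty is selected per
  training fold by stratified 5-fold inner CV maximizing held-out
  log-likelihood (ties toward the stronger penalty). The reported
  per-participant value is the *intercept-free* linear predictor `w·z(x)`
  of the fold's model: under leave-one-out the training-fold intercept
  encodes which class lost a member and is anti-predictive under the null
  (with an all-zero LASSO solution the intercept-only score yields AUC ≈ 0
  instead of 0.5), so it is excluded from the reported score.

Discrimination is summarized by the AUC of the cross-validated scores
(Mann–Whitney identity; ties count ½) with a permutation test: group labels
are permuted and the full pipeline — component extraction from the permuted
reference set, leave-one-out features, LOO LASSO — is re-run per
permutation; `p = (1 + #{AUC_perm ≥ AUC_obs}) / (n_perm + 1)`. The default
is 1,000 permutations (configurable; 10,000 is the conventional
high-precision setting). Reporting ANOVAs: two-way group × grade (Type II
sums of squares, via statsmodels OLS) and a two-factor repeated-measures
ANOVA of modality × confusability over the four condition metrics.

### Known property of LOO-CV AUC on congruency features

Even with matched reference sizes, every participant's features are
computed from overlapping reference data, so feature errors are correlated
across participants in a group-structured way. Leave-one-out training folds
can generalize from that structure, which makes the cross-validated AUC an
*optimistically biased point estimate* under the null (the classifier
itself is calibrated: on i.i.d. features its null AUC averages 0.49, and
the features carry no group mean shift). The permutation test is the valid
significance guard — permutations re-run the whole pipeline and reproduce
the same correlation structure, so the p-value remains calibrated. AUC
values should therefore be read together with their permutation p, not
against a fixed 0.5 chance line.

## The L1 logistic solver

The inner model of the LASSO metric is fit by an in-house accelerated
proximal-gradient (FISTA) solver with per-column adaptive restart,
vectorized over the whole penalty grid, JIT-compiled with numba. The
objective matches the common C parameterization
(`Σ_i log(1+exp(−y_i z_i)) + ‖w‖₁ / C`, intercept unpenalized), and the
test suite verifies coefficient agreement with sklearn's liblinear solver
on random instances. The reason for an in-house kernel is throughput: one
permutation test refits the model `(n_perm+1) × participants × (inner folds
+ 1)` times; at the default grid this is ~10⁵–10⁶ tiny fits per analysis,
where per-call overhead of a general-purpose implementation dominates by
orders of magnitude.

## Preprocessing and epoching conventions

* Average reference, then zero-phase 4th-order Butterworth high-pass at
  0.5 Hz, then zero-phase IIR notches (2 Hz bandwidth) at 50 and 100 Hz.
  Zero-phase application preserves FRP latencies; the filter realization is
  a declared convention of this package.
* Condition segments span [start − 2 s, end + 2 s], clipped to the
  recording; per-channel baseline over [−200, 0) ms before stimulus onset.
* Epoch grid: integer sample offsets k with −0.2·fs ≤ k < 0.5·fs
  (179 samples at 256 Hz). Fixation onsets map to the nearest EEG sample;
  epochs overrunning the segment are dropped and counted.
* Fixations are assigned to conditions by absolute timestamp against the
  condition windows from the EEG event markers, then re-expressed relative
  to stimulus onset; both streams are aligned through the same markers with
  no drift correction.
* Unequal fixation counts across participants are reconciled by truncating
  to the group-wide minimum per condition, keeping the earliest epochs
  (equal column counts are required by the pairwise covariances; early
  epochs avoid end-of-trial heterogeneity).
* No fixation-duration filter is applied by default (none is part of the
  method); min/max duration limits are available as options.

## Synthetic cohorts

The generator emulates the study design — two groups (reference "CAC" and
comparison "DYS") × two school grades, four conditions per participant —
without reproducing any real data:

* **Fixation sequences**: Gamma-distributed inter-fixation intervals
  (mean 350 ms, CV 0.3 — reading-like; strictly positive and right-skewed),
  onsets quantized to the 1,000 Hz eye-tracker grid; condition duration
  varies per participant around `letters_per_matrix × mean_ifi`
  (50 letters ≈ 17.5 s).
* **Planted source**: a Gaussian-bump evoked waveform (peak 170 ms after
  fixation onset, sd 40 ms, 10 µV) entering all participants' EEG through a
  shared unit-norm mixing vector, scaled by a per-group congruency gain
  (defaults 1.0 / 0.5) and jittered in latency per fixation (Gaussian,
  sd 10 ms, rounded to the EEG grid). The amplitude is set so the shared
  source is clearly detectable against the sensor noise (a dominant leading
  eigenvalue, λ1/λ2 ≈ 6 at S = 12, D = 32) — the operating regime of the
  method.
* **Noise**: Gaussian, 10 µV, exchangeable spatial correlation 0.2,
  temporally white. Real EEG background (1/f spectrum, ocular and muscle
  artifacts, inter-electrode distance-dependent correlation) is *not*
  modeled; passing tests therefore demonstrate the machinery of the method,
  not its robustness to real-world artifact structure.
* Grades alternate within group; an optional grade gain factor plants a
  grade main effect.

Everything is driven by one integer seed; identical configurations generate
bit-identical cohorts.

## Problem sizes

The reference study design (60 children, 64 channels, four conditions,
10,000 permutations) is emulated at reduced demonstration scales chosen for
desk-scale runtime: component recovery at S = 12, D = 32; group separation
at 15 + 15, D = 32; null calibration over 50 cohorts of 5 + 5 at D = 12 with
200 permutations; the acceptance script runs 10 + 10, D = 24, four
conditions, 200 permutations.

## Limitations

* The synthetic noise model is white and exchangeable; no artifact
  rejection is implemented (none is part of the method).
* LOO-CV AUC is optimistically biased under the null (see above); rely on
  the permutation p.
* Per-condition processing throughout; epochs are never pooled across
  conditions.
* Source localization and pointwise statistical comparison of temporal
  profiles are out of scope; the package exports the component bases,
  topographies and profiles as tables for external tools.
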