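# Methods

This note documents the models, algorithms and design choices behind
`p300sttc`: what the synthetic data emulates, how the CSTP filters and the
P300-STTCNet classifier are defined and trained, how the statistics are
computed, and where the open design decisions were resolved.

## The scientific setting

The package targets a two-group ERP paradigm: PTSD patients and healthy
controls (HC) perform a 5x5 character-matrix oddball task while 10 channels
of 10-20-system EEG (Fp1, Fp2, Fz, C3, Cz, C4, Pz, O1, Oz, O2) are recorded
at 1000 Hz. Rare target flashes elicit a P300 — a positive deflection
peaking ~300 ms post-stimulus, strongest fronto-centrally — whose amplitude
is reduced and latency delayed in PTSD. The pipeline quantifies these
spatiotemporal group differences and classifies single trials by group.

## Synthetic data generator

Clinical recordings of this kind are not shareable, so the package ships a
generator that emulates the paradigm's statistical structure. Per subject it
builds a continuous 10-channel recording:

* **Schedule** — trials of one target cue (1 s) followed by 9 flashes at
  0.5 s intervals, exactly one of which (seeded-random position) is the
  target; 2 runs x 2 blocks x 25 trials by default (100 target epochs per
  subject).
* **P300** — a Gaussian bump `a * exp(-(t - mu)^2 / (2 sigma^2))` added at
  each target flash, projected through a fixed fronto-central topography
  (Fz 1.0, Cz 0.9, C3/C4 0.8, Pz 0.6, Fp1/Fp2 0.4, occipital 0.3). The
  waveform shape is a modeling choice; only peak latency/amplitude semantics
  matter downstream.
* **Group parameters** — HC: latency 312 ms, amplitude 5 uV (at unit
  topography gain); PTSD: latency 415 ms, amplitude 2.5 uV (half of HC, a
  package choice for "overall lower"). Width sigma 45 ms for both.
* **Variability hierarchy** — each subject draws stable trait means around
  the group means (between-subject sd: latency 25 ms, amplitude 1 uV), and
  every trial jitters around the subject's traits (within-subject sd:
  latency 20 ms, amplitude 1 uV, width 5 ms). Each subject also draws
  stable multiplicative per-channel gains (lognormal, sigma 0.2), emulating
  electrode-impedance and anatomy differences.
* **Background** — pink (1/f) noise at 4 uV RMS per channel plus a 10 Hz
  alpha sinusoid of 2 uV with random per-channel phase.

The hierarchy is deliberate: the group statistics operate on subject
averages, whose dispersion is dominated by the between-subject traits
(yielding Fz effect sizes of order |d| ~ 1 at n = 12+12), while single-trial
classification depends on the within-trial signal-to-noise ratio. A
generator with only one noise knob cannot produce modest subject-level
effect sizes and strong single-trial separability at the same time; real
cohorts exhibit both because subjects differ in stable ways.

What the generator does **not** emulate: ocular/EMG artifacts (the
preprocessing artifact stage is a pass-through hook), non-stationary alpha,
volume-conduction correlations between channels' noise, session effects,
and visual rendering of the stimulus matrix. Consequences: the artifact
stage is untested against real artifacts, and raw-amplitude template
classifiers perform better here than on real EEG (see "Known limitations").

`SimulationConfig.noiseless()` zeroes every variability source and the
background; in that configuration the measured Fz peak latency equals the
configured group latency to within one sample, which anchors the
end-to-end tests (312 ms for HC; 416 ms for PTSD at the 4 ms epoch
resolution, the sample nearest the configured 415 ms).

## Preprocessing

Fixed stage order: band-pass 0.1-30 Hz (4th-order Butterworth applied
forward-backward; zero phase) -> average reference -> artifact hook ->
epoching (half-open [-100, 600) ms window around stimulus onset; 700
samples at 1000 Hz) -> baseline correction (subtract the per-trial,
per-channel mean over [-100, 0) ms) -> decimation to 250 Hz by keeping
every 4th sample (175 samples; safe because the 30 Hz low-pass sits far
below the 125 Hz post-decimation Nyquist). Baseline means are exactly zero
at the stage where the correction is applied; the decimated subsample of a
noisy baseline is zero only in expectation. Events too close to the
recording edge are dropped with a logged warning rather than zero-padded.

## CSTP

The common spatiotemporal pattern method learns a spatial filter bank
W (channels x M) and a temporal bank V (time x K) maximizing

    J(W, V) = tr(W' Sigma1(V) W) / tr(W' Sigma2(V) W),

with Sigma_c(V) the class-average spatial covariance of the temporally
filtered trials X V and R_c(W) the analogous time x time covariance of
W' X. Alternation: initialize V with the top-K eigenvectors of the pooled
temporal covariance; then repeat (a) solve the generalized eigenproblem
R1 v = mu (R1 + R2) v and keep K/2 eigenvectors from each end of the
spectrum, (b) solve Sigma1 w = lambda (Sigma1 + Sigma2) w and keep M/2 from
each end (the CSP convention: variance increases for either class are
captured). Numerical choices:

* Per-trial covariances inside the alternation are normalized by the raw
  trial energy tr(XX') rather than the projected energy. With
  projection-dependent normalization the two half-steps optimize
  differently-weighted objectives and J need not be monotone; with a
  projection-independent weight both half-steps ascend the same J.
* Each accepted update is additionally safeguarded: an update that would
  decrease J terminates the iteration (reported as converged — no
  eigendecomposition update can improve further). The recorded
  `objective_trace_` is therefore non-decreasing by construction.
* Eigenvectors are rescaled to unit-norm columns (generalized
  eigendecompositions return B-orthonormal vectors whose Euclidean norms
  are arbitrary and can be enormous, destroying the conditioning of the
  next half-step); signs are fixed by making the largest-magnitude entry
  positive; eigenvalue ties break by index.
* The covariance sum receives diagonal shrinkage
  (1-gamma) S + gamma (tr S / C) I with gamma = 1e-6 before every
  generalized eigendecomposition.
* Defaults M = K = 6, max 20 iterations, relative tolerance 1e-6.

Features per trial are normalized log-variances of the projected trial
Z = W' X V: `f_space[m] = log(var Z[m, :] / sum_m' var Z[m', :])` and the
analogous `f_time[k]` over columns, concatenated to M + K values. Each
block's exponentials sum to one and all features are non-positive.

The standalone `class_covariances` operation defaults to the projected
normalization tr(ZZ') (`normalize="projected"`); the fitter uses
`normalize="trial"`. PCA visualization uses column-centered SVD (via
scikit-learn) on flattened raw epochs or on CSTP features, no scaling.

## Group statistics

Per-subject target-trial averages feed three per-channel two-group
comparisons: window-mean amplitude, peak amplitude, and peak latency, all
within the 250-500 ms window (peak = maximum, ties to the earliest
sample). "Mean amplitude" reuses the peak window since no separate window
is specified anywhere. Tests are independent-sample pooled-variance
Student t-tests (conventional for equal group sizes) with Cohen's d =
mean difference / pooled sd, sign convention PTSD minus HC. Bonferroni
correction multiplies each p by the channel count and caps at 1; the table
reports raw and corrected columns and flags significance on the corrected
values at alpha = 0.05. Topography values are grand-average window means
per channel and group, plus an HC-minus-PTSD difference map.

## P300-STTCNet

Architecture (time samples are tokens):

1. **Channel prior** — a learnable gain per input channel, initialized to
   1.5 at Fz/C3/Cz/C4 and 1.0 elsewhere, updated during training.
2. **Embedding** — linear map of each 10-channel sample vector to d_model,
   plus sinusoidal positional encoding (attention alone is
   permutation-invariant over time and would discard latency, which is the
   core discriminative feature).
3. **Encoder** — 4 post-norm Transformer layers (multi-head attention ->
   add & layer-norm -> 2-layer ReLU FFN -> add & layer-norm). Attention per
   head is `softmax(Q K' / sqrt(d_k) + PriorMask) V`; the PriorMask adds a
   bias lambda (default 1.0) to every key column whose epoch time lies in
   the closed 250-450 ms window, shared across heads and layers. lambda = 0
   and unit channel gains reduce the model to a plain Transformer-CNN.
4. **CNN head** — the n x d_model representation as a one-plane image:
   conv 16@3x3 (valid) -> ReLU -> maxpool 2x2 -> conv 32@3x3 -> ReLU ->
   maxpool 2x2 -> flatten -> MLP -> 2 logits.

Defaults: d_model 64, 4 heads, FFN 128, MLP hidden 64, dropout 0.1.

The network and its reverse-mode gradients are implemented in numpy in
`p300sttc.nn`; gradient correctness is verified against central finite
differences (relative tolerance 1e-4) and against loop-level oracles for
attention and convolution. Training runs in float32 (float64 available via
`nn.default_dtype`).

Training: softmax cross-entropy minimized by Adam (lr 1e-3, batch 32,
optional decoupled weight decay), fully seeded and deterministic. Input
trials are normalized per trial and channel by the within-trial standard
deviation, which cancels the stable per-subject channel-gain nuisance
without using labels or subject identity. Training-time augmentation
(on by default) applies per-trial amplitude scaling U(0.7, 1.3), additive
Gaussian noise (0.2 of the normalized scale) and temporal shifts of up to
+-2 samples — standard EEG augmentations that suppress memorization of
subject-specific amplitude levels and noise patterns while preserving the
waveform shape and latency structure. Optional early stopping monitors
validation accuracy (ties broken by loss) on a stratified trial-level
split; a subject-level split is available (`val_by_group`) but is noisy at
small cohort sizes — with 2+2 held-out subjects the validation score can
anti-correlate with test-subject transfer when a validation subject's
traits resemble the other group, so the cross-validation harness trains
for a fixed epoch count instead. `cross_validate_sttcnet(ensemble=k)`
averages probabilities over k differently-seeded networks (soft voting)
when variance reduction is worth the compute.

## Evaluation

Folds partition subjects (never trials), class-balanced to within one
subject per class, seeded. CSTP is refit inside each training fold before
the SVM baseline sees its features (no leakage; a strict audit raises if
train and test subjects overlap). The SVM baseline is an RBF-kernel SVC
with C = 0.1 and gamma = 1/(n_features x feature variance); the raw-feature
control is the same SVC on per-feature-standardized flattened epochs.
Metrics (PTSD positive): accuracy, precision, recall, F1, ROC AUC from the
positive-class score, raw and row-normalized confusion matrices.
Aggregation across the k folds is mean +- 1.96 sd / sqrt(k) with the sample
standard deviation (ddof = 1).

## Problem sizes used by the test suite

End-to-end tests run the full cohort of 12+12 subjects but scale trial
counts and resolution to what the checks need: the classifier
cross-validation uses 50 target trials per subject (half the paradigm
default), epochs decimated to 125 Hz for the classifier comparison (the
P300, sigma 45 ms, is fully resolved; attention cost grows with the square
of the token count), and the default-width network trained for 12 fixed
epochs per fold. Statistical calibration uses 2000 Monte-Carlo replicates
with 3 channels and 8+8 subjects. The label-shuffle null check uses a
narrower network and 4 epochs (no architecture can learn shuffled labels).

## Known limitations

* The Gaussian-bump P300 and stationary noise make synthetic waveforms more
  homogeneous than real EEG even with trait and gain variability. One
  visible consequence: an RBF-SVM on standardized flattened raw epochs — a
  control that is weak on real data — acts as a near-matched-filter here
  and is a strong classifier (cross-validated accuracy ~0.67-0.76 across
  cohort seeds, comparable to the network's ~0.70). Passing or failing
  against this control on synthetic data therefore says little about the
  ordering on clinical recordings.
* Cross-subject CSTP features transfer poorly at this cohort size (the
  filters adapt to the specific subjects they are fit on); the CSTP+SVM
  baseline scores ~0.5 without leakage. This mirrors the known
  subject-specificity of CSP-family methods.
* A handful of simulated subjects draw traits on the wrong side of the
  group boundary (e.g. a PTSD subject with an early, large P300). Their
  trials are misclassified wholesale under subject-level CV, which puts a
  ceiling of roughly 0.8 on trial-level accuracy and makes fold scores
  lumpy at 3+3 test subjects per fold.
* The alternation objective J is evaluated on the full two-ended filter
  bank; it is a discriminability proxy, not a quantity the two-ended
  selection maximizes per step — hence the monotone safeguard.
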