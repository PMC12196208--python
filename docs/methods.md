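# Methods

## The pipeline

`eegfusion` implements a three-stage screening classifier for 19-channel
scalp EEG (10–20 montage, 500 Hz):

1. **Signal stage.** Recordings are band-pass filtered (4th-order
   Butterworth, 0.5–45 Hz, applied forward–backward so the phase is zero),
   optionally re-referenced to the mean of the two mastoid electrodes
   (A1, A2), and segmented into 4 s frames with 50 % overlap. Frames start
   at t = 0; trailing samples that do not fill a whole frame are dropped so
   every frame maps to fixed-size images. The frame count is
   `floor((N − L)/H) + 1` with `L = 4 s · fs` and hop `H = L/2`.
   Filtering is applied before re-referencing; both operations are linear
   and channel-wise, so the order only matters for numerical noise, and
   both steps are independently callable.

2. **Time–frequency stage.** Each channel of each frame becomes three
   128×128 grayscale images (see below), stacked over the 19 channels into
   three 128×128×19 tensors per frame.

3. **Classification stage.** One CNN per modality ("CNN1") is trained as a
   frame classifier and then frozen; its 50-unit penultimate dense layer is
   the modality's feature vector. The three 50-vectors are stacked into a
   3×50 single-depth image and classified by a second, smaller CNN
   ("CNN2"). Subject-level diagnoses come from voting over a subject's
   frame labels: on binary tasks the subject is positive iff the positive
   fraction is ≥ 0.5 (inclusive); on multi-class tasks the mode wins, with
   ties broken by highest mean predicted probability and then lowest class
   index.

## Time–frequency representations

**Spectrogram.** Squared-magnitude STFT with a 1 s Hamming window,
0.024 s hop and a 1024-point FFT. On a 2000-sample frame this yields
`k = (Nx − (M − R))/R = (2000 − 488)/12 = 126` segments, and the 1024-point
FFT at 500 Hz has 92 bins with centre frequencies inside [0.45, 45] Hz
(bins 1–92), i.e. a 92×126 matrix. The implementation is a sliding-window
`rfft`; tests verify it against a direct evaluation of the windowed DFT sum
at 1e-10 relative tolerance.

**Scalogram.** Magnitude of an analytic continuous wavelet transform on
122 geometrically spaced scales. The generalized Morse window
`a·ω^β·exp(−ω^γ)` (β = 20, γ = 3, the symmetric time-bandwidth-60 member
common in clinical EEG work) is normalised so that the wavelet at scale *s*
peaks at frequency 1/s with peak response 2; a unit-amplitude sinusoid at
the matched scale therefore has |CWT| ≈ 1. Scales span 1/45 s ≈ 0.022 s up
to 1/0.45 s, i.e. centre frequencies 45 Hz down to 0.45 Hz at ≈ 18.2
voices per octave — the only grid that simultaneously satisfies a 122-row
output and the stated frequency band. One shift per sample gives a
122×2000 matrix. The transform is FFT-domain filtering with reflect
padding of half a frame per side; tests check centre-frame values against
trapezoidal integration of the time-domain convolution integral (wavelet
waveform itself obtained by dense inverse-Fourier quadrature) within 1 %.

**Hilbert spectrum.** Empirical mode decomposition (cubic-spline envelopes
through local extrema with a two-extrema mirrored boundary extension,
Cauchy-type sifting stop SD ≤ 0.2, at most 10 IMFs, at most 50 sifting
iterations per IMF) followed, per IMF, by the analytic signal; the
instantaneous frequency is the central difference of the unwrapped phase
(one-sided at the endpoints, negative values discarded) and the
instantaneous amplitude is deposited into the nearest bin of the
0.45 : 0.35 : 44.9 Hz grid (128 points), summed over IMFs; frequencies more
than half a grid step outside the band are discarded. Reconstruction
(ΣIMF + residual = signal) is exact by construction and asserted at 1e-8
relative over random signals.

**Grayscale standardisation.** Each matrix is min–max normalised per image
(constant images map to all zeros) and bilinearly resized to 128×128 with
row 0 the lowest frequency. All three modalities are mapped on a *linear*
intensity scale by default. This was a measured design decision: the raw
spectrogram/scalogram span ~10 decades, so log10 compression followed by
per-image min–max squeezes a √2 band-power effect into one or two grey
levels out of 256 — in recovery experiments the extractors trained on
log-compressed images could not generalise to held-out subjects (chance
accuracy), while linear images carried the same effect as a first-order
brightness difference (0.93–0.95 held-out frame accuracy). Per-modality
log flags remain available (`build_stack(..., log_spectrogram=True, ...)`)
for visual inspection, where log scaling is genuinely more readable.

## Models and training

**CNN1** (per-modality extractor): four 3×3 same-padding convolution
blocks, each with batch normalisation, ReLU and 2×2/stride-2 max-pooling,
with 32/64/128/256 filters; four halvings take 128 → 8 spatially. The head
is flatten → dense(10) → dense(50) → softmax; the 50-unit layer
(post-activation) is the feature vector. The unusual 10 → 50 expansion is
kept deliberately, with `widen_feature_first=True` available to flip the
order for ablations. **CNN2** (fusion classifier): the 3×50 feature image
through two 3×3 convolution blocks (64/128 filters) pooling only along the
50-axis (1×2, so the 3-row modality axis survives), then dense(10) →
softmax.

Training uses Adam (η = 1e-3, β₁ = 0.9, β₂ = 0.999), categorical
cross-entropy, L2 penalty λ = 1e-4 on convolution and dense weights,
batch 32, a reduce-on-plateau schedule (×0.5 after 10 stagnant validation
epochs, floor 1e-6), early stopping (patience 20, max 150 epochs,
best-validation weights restored) and image-space augmentation (random
rotation ±15°, scale 0.9–1.1 with zero fill, additive Gaussian noise
σ = 0.01). All randomness — initialisation, shuffling, augmentation —
derives from one integer seed; runs are bit-reproducible at a fixed BLAS
thread count.

The layers, Adam, and the training loop are implemented in-package on
NumPy (`eegfusion.nn`): 3×3 convolutions are computed as one contiguous
GEMM over the padded tensor covering all nine taps, followed by shifted
accumulation, which keeps the arithmetic in BLAS; gradients are verified
against finite differences in the test suite.

## Synthetic cohorts

The generator emulates the structure of a resting-state dementia-screening
cohort: per subject, 19 channels of 1/f^χ background noise (χ = 1,
unit-variance shaped Gaussian noise, 10 µV SD) plus one
amplitude-modulated oscillator per canonical band (delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30 Hz). Baseline relative band powers
(1 : 1 : 2 : 0.5 for delta : theta : alpha : beta) describe an eyes-closed
adult posterior rhythm; each oscillator's power is `osc_to_noise = 6`
times the background variance times its relative weight. Oscillators have
random phase, slow (~0.1–0.4 Hz) sinusoidal amplitude modulation and a
slow wander of the instantaneous frequency (smoothed random walk, 15 % of
the band width, ~1 s timescale). The wander matters: with a fixed sharp
per-subject frequency, CNNs memorise subject-unique spectral line
positions instead of class structure — an artifact real EEG, whose peak
frequencies drift, does not offer.

Class signatures scale with `effect_size` e:

* **A** (AD-like): diffuse slowing — delta and theta power ×2^(e/2), alpha
  and beta ×2^(−e/2); the theta/alpha power ratio doubles at e = 1.
* **F** (FTD-like): frontal-only theta ×2^e and alpha ×2^(−e/2) on Fp1,
  Fp2, F3, F7, F8, giving channel-importance analyses a known ground
  truth.
* **C**: baseline.

Between-subject variability is lognormal per band (`subject_sd`, default
0.1 on log power) plus a 5 % per-channel amplitude jitter. The default was
set by a power argument: the between-class separation of the
(theta − alpha) log-power difference at e = 1 is ln 2 ≈ 0.693 against a
between-subject SD of √2·`subject_sd`; at 0.1 the Bayes subject-level
error is below 1 %, so a correct pipeline can realistically recover the
effect from a compact cohort, while at 0.2 even the optimal classifier
errs on ~11 % of subjects and recovery experiments would measure the
generator, not the pipeline. Signals are deterministic given
`(spec.seed, subject_seed)`.

What the generator does *not* emulate: volume conduction and realistic
inter-channel correlation, artifacts (blinks, EMG, electrode pops),
non-Gaussian microstructure, medication or vigilance effects. Passing the
synthetic studies therefore demonstrates that the machinery — transforms,
feature learning, fusion, voting, evaluation — recovers a planted
band-power effect across subjects; it does not predict clinical accuracy
on real cohorts.

## Evaluation protocols and statistics

Stratified subject-disjoint k-fold and leave-one-subject-out protocols
keep all frames of a subject on one side of every split; inner
validation (for scheduling/early stopping) splits off 20 % of training
*subjects*. Frame-level confusions are concatenated across held-out
subjects; subject-level confusions come from the votes. Sensitivity is
the recall of the disease class and specificity the recall of controls;
metrics with zero denominators are reported as missing, never as 0.

Feature-similarity analysis computes the 3×3 Pearson matrix between the
modality feature vectors as covariance over the product of standard
deviations; zero-variance vectors yield flagged missing entries.

Channel importance min–max normalises per-class single-channel
sensitivities across the 19 electrodes (an all-equal row maps to all ones
with a degeneracy flag). The paired-comparison battery gates on
Shapiro–Wilk normality of the differences (α = 0.05) to choose paired
t vs Wilcoxon signed-rank, reports paired Cohen's d with the 0.2/0.5/0.8
labels, applies Bonferroni over the comparisons requested in one call,
and offers repeated-measures ANOVA with Tukey HSD for ≥ 3 groups.
Bootstrap confidence intervals are seeded percentile intervals
(n = 1000 by default); BCa was deliberately not used.

## Desk-scale study sizes

The two built-in synthetic studies are sized to run in minutes on one CPU
while exercising every stage end to end:

* **Recovery study**: 8 subjects/class (A vs C), 30 s recordings,
  10 frames/subject, effect size 1.0, 4-fold subject-stratified CV (each
  of the 16 subjects scored exactly once by a model that never saw their
  frames). Study models use a reduced profile: a 2×2 input pooling, 8/16/
  32/64 conv filters, batch 16, 12 epochs, no augmentation. The reduced
  width trades capacity for speed; the architecture topology (four conv
  blocks, dense 10 → 50 head, frozen extractors, CNN2 fusion) is the full
  pipeline's.
* **Null control**: identical machinery at effect size 0 (6 subjects/
  class, 8 frames, 3 folds) — subject accuracy must fall inside the 95 %
  binomial band of chance.
* **Channel-importance study**: F vs C with the frontal-only signature
  (5 subjects/class, 8 frames); each channel's three modality images are
  stacked into a 128×128×3 input for a compact probe CNN (two conv
  blocks, shared folds across channels) rather than the full
  three-extractor pipeline — 19 channels × 5 folds = 95 trainings make
  the full pipeline impractical here, and the probe preserves the
  property under test (identical conditions per channel, per-class
  sensitivity, min–max normalisation).

## Numerical choices and degenerate inputs

* Argmax ties in frame classification break toward the lower class index.
* Constant TFR matrices map to all-zero images; constant signals yield no
  IMFs and an all-zero Hilbert spectrum.
* EDF output is 16-bit with per-channel symmetric physical scaling and
  1 s records; recordings are truncated to whole seconds on write.
* The L2 penalty is `λ·Σw²` (gradient `2λw`), applied to weights only,
  not biases or batch-norm parameters.
* Batch-norm running statistics use momentum 0.1; on very short schedules
  the desk-scale profile compensates with smaller batches (more updates).
* `bandpass_filter` rejects edges at or above Nyquist; the 0.5 Hz edge has
  multi-second filtfilt transients, which tests account for by discarding
  generous margins.

## Known limitations

* The NumPy training loop is single-process and CPU-bound; full-width
  training on realistic cohort sizes is out of scope.
* EMD is the classic single-realisation algorithm; ensemble variants and
  mode-mixing mitigation are not implemented.
* The EDF writer covers the minimal subset of the format the pipeline
  needs (EDF, not EDF+; no annotations).
* Real-data performance claims are out of scope: the synthetic studies
  validate machinery, not clinical effect sizes.
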