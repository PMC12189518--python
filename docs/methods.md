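# Methods

## Problem and pipeline

The package classifies single trials of left- versus right-hand motor imagery
(MI) from three sensorimotor electrodes (C3, Cz, C4) sampled at 250 Hz. The
physiological signal is the lateralised modulation of sensorimotor rhythms:
imagery of one hand attenuates the contralateral mu rhythm (8–13 Hz;
event-related desynchronization, ERD) and enhances the contralateral beta
rhythm (13–30 Hz; event-related synchronization, ERS). The pipeline converts
each cue-locked 5-s trial into a 250 × 250 × 3 tensor of per-channel Morlet
scalogram images (the channel-dependent multilayer time-frequency
representation, CDML-EEG-TFR) and classifies it with a frozen convolutional
trunk plus a small trained head.

## Trial extraction

Trials are anchored at the cue-onset marker and span the half-open window
[onset, onset + 5 s) — in the cue-paced paradigm the cue falls at t = 3 s of
an 8–9 s trial and imagery runs to 7.5 s, so the window covers the full
imagery period plus a short tail. Windows that overrun the recording are
rejected with a logged warning rather than zero-padded: padding would
fabricate signal and bias the scalogram's right edge. Channels are always
reordered to (C3, Cz, C4), matching a left–midline–right scalp traversal;
depth position in the stacked tensor therefore always means the same
electrode. All cue-marked trials are kept; no artifact screening is applied.

## Rhythm filter

A second-order Butterworth band-pass, 8–30 Hz, applied per channel. The
default is zero-phase (forward–backward) application so that time-frequency
energy is not delayed relative to the cue; this squares the magnitude
response, and the test oracle accounts for it. A causal single-pass mode is
selectable. Because a 5-s window holds few cycles at the 8 Hz edge, the trial
is reflect-padded by 1 s per side before filtering and trimmed after.

## Continuous wavelet transform

The transform is W(s, τ) = s^(−1/2) ∫ x(t) φ*((t − τ)/s) dt with the Morlet
atom φ(u) = π^(−1/4) e^{iω₀u} e^{−u²/2}. Numerical choices:

- **ω₀ = 6** (centre frequency f_c = ω₀/2π ≈ 0.9549). This is the standard
  choice for which the non-zero-mean correction of the Morlet atom is
  negligible (~e^{−18}); f_c is configurable.
- **Scale grid**: 250 geometrically spaced scales with endpoints pinned
  exactly to s_min = f_c·f_s/f_max and s_max = f_c·f_s/f_min for the 8–30 Hz
  band. Geometric spacing gives constant relative frequency resolution
  (ratio ≈ 1.0053 between rows); 250 rows match the 250-pixel image height,
  a nominal (30−8)/250 = 0.088 Hz per row.
- **Evaluation**: FFT convolution per scale, kernel truncated where the
  Gaussian envelope falls below e^{−32} (8 scale-widths), with the two series
  endpoints corrected from rectangle to trapezoid weights. The fast path
  matches direct trapezoidal quadrature of the integral to ~1e−15 relative
  error; the test suite enforces 1e−6 on ≤ 256-sample signals.
- **Edges**: the signal is mirror-extended by one maximal wavelet support and
  trimmed after transforming; no cone-of-influence mask is applied, so the
  rendered maps are full-width.
- **Ridge localization**: the s^(−1/2) normalisation weights scalogram rows
  by √s, which biases the raw-magnitude ridge of a pure tone low by about
  1/(2ω₀²) ≈ 1.4% — a couple of geometric grid steps. `ridge_frequency`
  therefore divides rows by √s (the amplitude-flat view) before taking the
  argmax, which is bias-free; single tones then localise within one grid
  step across the band. Simultaneous tones can interact through spectral
  overlap and may shift each other's ridge slightly beyond the single-tone
  bound.

## Image rendering and stacking

Magnitude |W| is rendered by default (|W|² selectable). The 1250 time samples
are reduced to 250 columns by averaging consecutive blocks of five —
anti-aliased, deterministic and bit-stable, unlike interpolation. Each image
is min–max normalised to [0, 1], making the representation invariant to
overall signal gain; a constant scalogram renders as a uniform 0.5 image by
convention. The three channel images are stacked depth-wise in (C3, Cz, C4)
order. The stacking order is configurable: with a trunk pretrained on natural
images the assignment of electrodes to colour planes is a genuine
hyperparameter. Single-channel ablation inputs replicate one channel's image
across all three layers, preserving the trunk's input shape.

## Classifier

Backbones EfficientNet-B0 (default), ResNet50 and Inception-v3 are
implemented in numpy with parameter structures identical to the published
reference implementations — including batch-norm moving statistics, so the
full counts are 4,049,571 / 23,587,712 / 21,802,784 for the trunks without
tops, and 4.21 M for EfficientNet-B0 with the head. The head is global
average pooling → dense(128, ReLU) → dropout(0.5) → dense(2, softmax);
164,226 trainable parameters on a 1280-wide trunk.

Design points:

- **Frozen trunk.** The backbone is a fixed feature extractor: batch norm
  always runs in inference mode (updating its statistics would silently
  violate freezing), and a checksum of every trunk parameter is asserted
  unchanged across training. Because the trunk never changes, features are
  computed once per tensor and the head is optimised on the cached feature
  matrix — mathematically identical to full forward passes per batch.
  Full-network fine-tuning is deliberately unsupported.
- **Feature standardisation.** A randomly initialised trunk emits features on
  an arbitrary and very small scale (squeeze-excitation gates and swish
  shrink activations multiplicatively through 16 blocks). A per-feature
  affine standardisation — mean and standard deviation computed once from the
  training set — is applied between pooling and the first dense layer. These
  are calibration statistics, not trained parameters; without them the head's
  logits cannot reach decision scale in any reasonable number of Adam steps.
- **Input handling.** 250 × 250 inputs feed the fully-convolutional trunk
  directly (global pooling makes it size-agnostic); no resizing to the
  pretraining resolution. The pretraining corpus' channel normalisation is
  applied only when pretrained weights are loaded — for a random trunk those
  statistics are meaningless.
- **Training.** Adam (lr 0.001), cross-entropy, batch size 32, 150 epochs by
  default; the epoch snapshot with minimum validation loss is kept.
  Pretrained weights are only ever consumed from a local `.npz` keyed by
  layer path; nothing is downloaded.
- **Prediction.** Dropout is disabled at inference; the class order is
  (left, right) and exact ties resolve to "left".

## Cross-validation

Per subject: ten stratified, disjoint folds (class proportions per fold
within one sample). For each fold a fresh head is trained on the other nine
tenths, from which a 10% stratified inner validation split is held out for
minimum-validation-loss model selection — using the test fold for selection
would leak. Accuracy is the fraction of correct argmax predictions; a
subject's score is the mean over folds and the headline number the unweighted
mean over subjects. Fold assignment, head initialisation, dropout masks and
batch order all derive from one seed, making a run bit-reproducible on one
machine.

## Synthetic sessions

The simulator generates the full recording (not just epochs): 160 balanced,
randomly ordered trials of 8.5 s, cue at 3 s, imagery window 3–7.5 s, 1–2 s
rest between trials, with cue markers; sessions round-trip through the
bundled 16-bit EDF writer and an `_events.tsv` sidecar so the file-based
entry path is exercised end to end.

Each channel carries unit-variance 1/f background noise scaled to
`noise_sigma`, plus mu- and beta-band oscillators realised as band-limited
filtered white noise — realistic broad spectra with analytically controllable
band power, unlike pure sinusoids. During the imagery window the channel
contralateral to the imagined hand has its mu amplitude multiplied by
(1 − `erd_depth`) and beta by (1 + `ers_gain`), with 0.25-s raised-cosine
ramps. Cz is deliberately left unmodulated so single-channel ablations have a
known ordering (C3/C4 informative, Cz at chance). Defaults: mu 7 µV RMS,
beta 3.5 µV RMS, `erd_depth` 0.6, `ers_gain` 0.3, `noise_sigma` 20 µV. The
noise level was calibrated once so that the default-configuration
cross-validated accuracy falls in the 0.80–0.95 band (measured ≈ 0.89) — a
regime that exercises rather than saturates the classifier; at `erd_depth`
0.9 with `noise_sigma` 4 the problem is near-perfectly separable, and at zero
contrast the two classes are generated by the identical recipe.

What the simulator does **not** model: volume conduction between electrodes,
ocular/muscular artifacts, non-stationary baseline drift, inter-subject
variability of rhythm frequency and ERD strength, and Cz physiology. Passing
tests on synthetic sessions therefore demonstrate that the pipeline recovers
a lateralised band-power contrast embedded in 1/f noise — they do not certify
accuracy on real recordings, which is why the benchmark workflow
(`scripts/reproduce_bci2b.py`) is shipped separately and requires the real
dataset and pretrained weights.

## Test and acceptance problem sizes

Unit tests run a reduced geometry (64 scales / 64 × 64 images, 20-trial
sessions) that exercises every code path; the acceptance tests run the full
250 × 250, 160-trial geometry with the classifier checks at 20 epochs, which
head-only optimisation converges within comfortably. The independent oracles
are: direct trapezoidal quadrature of the wavelet integral, the closed-form
prewarped Butterworth magnitude, Welch band-power ratios for the simulator's
ERD/ERS, an independent wavelet library's ridge location, and exact binomial
null bands for permutation tests.

## Known limitations

- Training requires the frozen-trunk regime; there is no fine-tuning path.
- The numpy forward pass is single-threaded BLAS-bound: roughly a second per
  250 × 250 tensor for EfficientNet-B0, so a full 9-subject evaluation is an
  hours-scale batch job rather than interactive.
- The EDF writer targets round-tripping of simulator output (16-bit, 1-s
  records, zero-padded tail); it is not a general-purpose EDF+ exporter.
- With a random frozen trunk the features are a fixed nonlinear projection;
  nothing adapts the representation to EEG statistics, by design.
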