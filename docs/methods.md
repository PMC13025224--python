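# Methods

This note documents the models and procedures implemented in `eegtfr`,
the numerical choices behind them, and what the synthetic-data tests do
and do not demonstrate.

## Problem setting

Pre-treatment resting-state EEG (19 channels, 10–20 montage, 256 or
500 Hz) is used to predict whether a patient with depression will
respond to a course of therapy (SSRI pharmacotherapy or rTMS).  Each
recording is turned into a set of time-frequency images — one per
15-second epoch and channel — and a CNN classifies each image as
responder (R) or non-responder (NR).  Subject-level predictions are
obtained by majority voting over a subject's images.

## Preprocessing

Order of operations: zero-phase band-pass (0.5–70 Hz, 4th-order
Butterworth) and 50 Hz notch (2nd-order IIR, Q = 35), both applied
forward–reverse so the group delay is zero; common average reference;
segmentation into non-overlapping 15-s epochs (trailing remainder
discarded); optional peak-amplitude epoch rejection (off by default);
multiscale PCA denoising; polyphase resampling of every epoch to a
common 512 Hz.  The amplitude-rejection option is a deliberately simple
stand-in for subspace-reconstruction artifact removal — it drops an
epoch whose peak absolute amplitude exceeds a threshold, nothing more.

**MSPCA.**  Each epoch is wavelet-decomposed per channel (sym4,
level 9; epochs must have at least 2⁹ samples).  Detail coefficients
are soft-thresholded with the universal threshold σ·√(2 ln N), with σ
estimated per channel as MAD/0.6745 of the finest-scale details and N
the epoch length.  PCA across channels is applied to the approximation
coefficients and again to the reconstructed signals, in both cases
retaining components whose eigenvalue exceeds the mean eigenvalue
(Kaiser's criterion).  Two behaviours of this estimator are worth
knowing: (i) the universal soft threshold shrinks large signal
coefficients by the threshold too, so a narrow-band oscillation whose
wavelet coefficients sit near the threshold (e.g. an alpha tone at 0 dB
broadband SNR) is denoised only mildly, while slower rhythms with
larger per-coefficient amplitude gain several dB; (ii) the Kaiser rule
discards below-mean eigencomponents, so multichannel signals whose
components have very unequal per-scale power lose some cross-scale
leakage energy.  The tests assert exactly these behaviours.

## Time-frequency representations

**CWT scalogram.**  Analytic Morlet wavelet (centre frequency
ω₀ = 6 rad), computed in the FFT domain with a one-sided kernel
2·exp(−(sω−ω₀)²/2) for ω > 0, so negative frequencies are exactly
suppressed.  The kernel is L1-normalised: equal-amplitude tones produce
equal magnitude on every row.  Rows are log-spaced at 12 voices per
octave covering 2–60 Hz (59 rows); the image intensity is the raw
magnitude |W(a,b)|, not dB.  The signal is reflect-padded by four times
the largest scale before the FFT to suppress wrap-around.  Note the
ω₀ = 6 Morlet has a relative frequency resolution of 1/6 — about three
voices — so a tone's energy spreads over a few adjacent rows by design.

**VMD spectrogram.**  Each epoch channel is decomposed into K = 20
band-limited modes (below); each mode's complex STFT (Hamming window of
256 samples, overlap 250 → hop 6 samples, 7680-point FFT at 512 Hz) is
accumulated as a complex sum and the magnitude of the sum, restricted
to 0–60 Hz, is the image.  By linearity the complex sum equals the
STFT of the summed modes; the tests hold this identity to 1e-10.

**Fusion.**  The CWT and VMD images of the same subject/epoch/channel
are bilinearly resampled to a common grid, each min-max normalised to
[0, 1], and averaged pixel-wise.  A constant image normalises to zeros
(division-by-zero guard).

**Rendering.**  Magnitude grid → per-image min-max → 256-level jet
lookup → bilinear resize to the target square size → borderless RGB
PNG, named `<subject>_<epoch>_<channel>_<repr>.png`.  Rendering is
array-to-pixel, not a plotting canvas, so images are resolution-exact
and bit-reproducible.

## Variational mode decomposition

VMD decomposes a signal into K modes u_k with centre frequencies ω_k by
minimising the summed bandwidth of the demodulated analytic modes
subject to reconstruction.  The augmented-Lagrangian saddle point is
found by alternating closed-form updates on the one-sided spectrum:

* û_k ← (x̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)
* ω_k ← ∫ω|û_k|²dω / ∫|û_k|²dω  (spectral centre of gravity)
* λ̂ ← λ̂ + τ(x̂ − Σ û_k)  (skipped at τ = 0)

until Σ_k ‖û_k⁽ⁿ⁺¹⁾−û_k⁽ⁿ⁾‖²/‖û_k⁽ⁿ⁾‖² < ε, with a `max_iter` guard
(500).  Defaults: K = 20, α = 2000, τ = 0 (the noise-robust variant —
exact reconstruction is not enforced), ε = 1e-7.  Frequencies are kept
normalised (cycles/sample) inside the solver and converted to Hz at
the interface.  Centre frequencies initialise uniformly over the lower
quarter of the spectrum (a `zero` option exists); the signal is
half-length mirror-extended at both ends and centre-cropped after,
which suppresses boundary artefacts.  Modes are sorted by ascending
ω_k on output.  Two practical notes: on broadband noise with K = 20
the stopping criterion may not fire within 500 iterations (the result
is still returned, flagged unconverged), and a very large α with
far-off initial centre frequencies can strand a mode — both are
inherent to the method, not solver defects.

## Classifiers

All models map 224×224 RGB images (ImageNet-normalised) to two logits;
index 0 is the responder class.  Because no deep-learning framework is
part of the dependency footprint, the layers (grouped convolution via
im2col, batch/layer norm, pooling, multi-head self-attention, dropout)
run on a small reverse-mode autodiff engine over NumPy included in the
package (`eegtfr.nn`), with gradients verified against finite
differences in the test suite.

* **resnet18** — standard 18-layer residual network (widths
  64/128/256/512, two basic blocks per stage).
* **mobilenet_v3** — MobileNet-V3 Large: inverted-residual bottlenecks,
  hard-swish, squeeze-and-excitation.
* **efficientnet_b0** — MBConv blocks with SiLU and SE.
* **tinyvit_hybrid** — ResNet-18 trunk through its last convolutional
  stage (B×512×7×7), flattened to 49 tokens of dimension 512, plus
  learnable 1-D positional embeddings, two pre-norm transformer blocks
  (8 heads, MLP ratio 4 → inner width 2048, dropout 0.1), layer norm,
  mean pooling over tokens, linear head.
* **tiny_cnn** — two conv layers (widths 16 and 32, each with batch
  norm and ReLU), pooling over the *time* axis only, and a linear head
  on the channel × frequency-row features; a fast-experiment model, not
  part of the evaluated set, with a configurable input size (default
  32 px).  Two design points matter: the widths are chosen so the model
  trains reliably within the 8-epoch budget, and the pooling keeps the
  frequency axis intact — global average pooling would reduce a
  time-frequency image to position-free statistics, leaving the model
  unable to tell which rows (bands) are active, which in practice
  caps its accuracy and makes training fragile.

ImageNet-pretrained weights are an external binary asset and are not
bundled; models initialise randomly (`pretrained=True` raises), and a
locally available checkpoint can be loaded with `Module.set_state`.

**Training.**  AdamW (lr 1e-4, weight decay 1e-4), cosine annealing
over T_max = 8 epochs to lr 1e-6, batch size 32, cross-entropy, at most
8 epochs with early stopping on validation loss (patience 3); the
weights at minimum validation loss are restored.  The per-fold seed is
42 + 100 × fold index.  For the tiny_cnn used in desk-scale runs the
learning rate is raised to 1e-2 (its own choice; the tiny model
underfits badly at 1e-4 within 8 epochs).

## Evaluation protocol

Two 6-fold strategies.  *Image-level*: all images pooled, stratified by
class; within each fold the non-test images are split 90/10
(stratified) into train/validation.  *Subject-level*: each class's
subjects are spread over the folds as evenly as possible with the
remainder in the earlier folds (12R/18NR → (2R, 3NR) per fold;
23R/23NR → (4R, 4NR) ×5 + (3R, 3NR)), so every subject is tested
exactly once and never contributes images to both sides of a fold; the
non-test subjects split 90/10 by subject.

Metrics are the five confusion-matrix percentages (accuracy, precision,
recall, specificity, F1) with responder positive; a 0/0 ratio is
reported as 0 and flagged.  Subject-level accuracy is majority voting
over each subject's image predictions — exact ties break to NR (the
clinically cautious call) and are counted — with a t-based 95% CI over
the six fold accuracies (the standard small-n interval).  Per-channel
analysis repeats the vote restricted to each channel's images.  Model
and representation comparisons use the exact two-sided Wilcoxon
signed-rank test on per-fold accuracies (n = 6 is far too small for the
normal approximation); zero differences are dropped, and an all-zero
difference vector returns p = 1 with a warning.  No multiplicity
correction is applied to the pairwise p-matrix.

## Synthetic data

The generator emulates what the pipeline needs and no more: per channel
a 1/f background (β = 1, filtered white noise), band-limited Gaussian
oscillations in the five classical rhythms with eyes-closed-like
relative amplitudes (alpha-dominant), optional 50 Hz line interference
with random phase, and white sensor noise.  The class effect is a
multiplicative band-power scaling applied only at configurable effect
channels (defaults: 3:1 alpha power at O1/O2), so channels off the
effect set carry no class information by construction.  It does *not*
model volume conduction, dipole geometry, inter-channel correlation
structure, non-stationarity, or real artifact morphology — so a passing
end-to-end test shows the pipeline recovers a known localised spectral
effect, not that it would attain any particular accuracy on clinical
recordings.  Channel labels are the real 19-electrode 10–20 names so
per-channel analyses read naturally.  Fixed seeds give bit-identical
cohorts.  An EDF writer (16-bit, 1-s records) lets the real-data reader
path be exercised round-trip in tests.

## Desk-scale study sizes

The end-to-end study run by the acceptance script and test suite uses
20 subjects (10 R / 10 NR) at the default 300 s / 256 Hz → 20 epochs ×
19 channels = 380 CWT images per subject, rendered at 64 px and fed to
the tiny_cnn at the full 64 px under subject-independent 6-fold CV with
the 8-epoch training budget.  (Down-sampling the input further to
32 px blurs the ~5-row alpha band of the 59-row scalogram enough to
cost several points of per-image accuracy, which the majority vote then
amplifies.)  These sizes are the package's choice of a
desk-scale experiment: large enough that a binomial test at p < 0.01
can detect above-chance subject accuracy, small enough to run on one
CPU in minutes.  One property of this design worth noting: 17 of 19
channels carry no class signal, and their image predictions are
correlated within a subject (the common average reference injects a
shared component into every channel), so the pooled majority vote is
diluted substantially below the per-channel accuracy of O1/O2 — the
same reason the per-channel analysis exists in the first place.

## Known limitations

* Numerical equality with MATLAB's `vmd`/`cwt`/`wmulden` is not
  promised; the algorithms follow the published update rules, not
  MATLAB internals (initialisation and boundary handling differ).
* The NumPy training stack is CPU-bound and meant for desk-scale
  experiments; fine-tuning the full 224-px architectures on tens of
  thousands of images is out of its intended range.
* The EDF writer covers continuous 16-bit recordings with integral
  sampling rates only.
* Majority-vote ties are possible whenever a subject has an even
  number of images; the NR tie-break is a convention, and the tie count
  is reported so its influence is visible.
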