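# Methods

This note records the modeling and numerical choices behind the package:
what is computed, which knobs matter, what the synthetic benchmark does and
does not establish, and where the design was genuinely open.

## Pipeline overview

A *trial* is one stimulus/response recording with three synchronized
streams (video frames or frame features, an audio waveform, multi-channel
EEG) and an integer emotion label. Processing is block-based: trials are
cut into windows of `block_len_s` (default 4 s) stepping by
`block_len_s × (1 − overlap_frac)` (default 50 % overlap), after an
optional fixed per-modality lag `lag_s` (default 0; the lag is a simple
stream-trim shim — estimating lags from data is out of scope). Every block
inherits its trial's label. A trial shorter than one block is an error,
never silently empty.

## Preprocessing

**EEG band power.** Per block and channel, each of the five classical bands
(delta 0.4–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz) is
isolated with a 4th-order Butterworth bandpass applied forward–backward
(zero phase; effective attenuation doubled), and the band power is the mean
squared amplitude of the filtered signal. One PSD vector per block per
channel; no sub-windowing. The sampling rate must exceed twice the highest
band edge, and the block must cover at least one period of the lowest band
edge (2.5 s at 0.4 Hz). Filtering, not Welch averaging, was chosen so the
band powers sum to at most the total signal power up to filter leakage — a
property the tests verify against a direct DFT periodogram.

**Audio.** Log-Mel spectrogram: 50 ms Hamming window, 10 ms hop, magnitude
squared rfft, 20 triangular Mel filters (HTK scale, 0 to Nyquist), natural
log with an additive floor `log_floor = 1e-10` (configurable) so silence
maps to `log(1e-10)` rather than −∞. Audio is expected at 16 kHz; WAV
input (PCM int or float) is normalized to [−1, 1] on load.

**Audio presence.** Block energy is `Σ x²`. Three threshold modes:
`absolute` (threshold given directly), `percentile` (threshold is the given
percentile of the batch energies) and `relative` — the default — where the
threshold is `0.05 ×` the median batch energy. The relative rule was
chosen as the default because a fixed low percentile mislabels part of the
silent cluster whenever the silent fraction exceeds that percentile; a
fraction of the median separates a silent minority from the speaking
majority regardless of how large the minority is.

## Encoders

**Spatial encoders** are pluggable through a registry: any callable that
declares an `output_width` and maps a preprocessed block to a `(T_m, D_m)`
feature sequence. The shipped reference encoders are deterministic, seeded,
*untrained* nonlinear projections — they play the architectural role of
large pre-trained backbones (frozen feature extractors) while keeping the
package self-contained; published encoders attach through the same
contract. Reference defaults: video subsampled to 16 frames per block;
audio spectrogram averaged into 16 temporal chunks; EEG band power
log-compressed, densely mapped, and repeated to 4 time steps so the
temporal encoder sees a sequence. All three emit width 32.

**Temporal encoder.** A Residual-TCN shared across modalities (one set of
weights; this also guarantees the common output width D the projection and
attention stages require). Each of the 4 blocks applies one dilated causal
convolution (kernel 3; dilations 1, 2, 4, 8 → receptive field
1 + 2·15 = 31), batch normalization, ELU, dropout 0.5 and a residual
connection with a 1×1 linear shortcut when widths differ. One convolution
per block is the default (two are configurable). Convolutions use causal
left zero-padding so output length equals input length. Batch statistics
are taken over batch and time in training; evaluation uses running
statistics, which also makes eval-mode outputs deterministic and strictly
causal — the causality test runs in eval mode. A per-sample layer-style
normalization fallback (`norm_mode="layer"`) exists for batches too small
for stable batch statistics. Default representation width D = 128.

## Contrastive objective

Embeddings: mean pooling over time (the representation is pooled before
projection; last-step pooling is available), then a bias-free linear map to
the shared space (P = 64) and L2 normalization (default; raw embeddings are
available but the margin α then loses its cosine interpretation).

The ratio losses (intra- and inter-modal) as printed use raw inner products
inside a logarithm, which can be nonpositive. The default *softened* mode
maps every similarity through `exp(s/τ)` (τ = 0.1) — preserving the ratio
structure while keeping the loss finite and defined; `literal_mode=True`
evaluates the raw form and raises a domain error rather than returning NaN.
The alignment term pulls each sample's cross-modal similarities to a margin
α = 0.8 (not 1.0: modalities should agree, not collapse onto each other).
λ₁ = λ₂ = λ₃ = 1 by default. The anchor expectation is the arithmetic mean
over all valid anchors in the mini-batch and over the three anchor-modality
roles; positive/negative counts vary with batch composition. Anchors with
no surviving positive are skipped and counted, never fabricated; the
skip counts are part of the per-step JSON-lines log. Audio embeddings of
silent blocks are removed before pair construction in every term, and a
silent-audio anchor is itself skipped.

## Fusion and classification

Six directed attention results in fixed order a→v, v→a, e→v, v→e, e→a,
a→e, where the direction x→y means "y's sequence queries x's": queries
come from the first MHA argument, keys/values from the second. Heads: 4,
with `d_k = D / heads`. The printed score formula omits the softmax but the
mechanism invoked is standard multi-head attention, so row-softmax of
`QKᵀ/√d_k` is the default; `raw_scores=True` reproduces the unnormalized
variant for study. Parameters are independent per direction (6 blocks);
a shared-parameter mode exists for symmetry checks. Each result is mean-
pooled over query time (configurable to last/max) — pooled vectors rather
than full sequences are concatenated, since the modality sequence lengths
differ and the fused vector feeds a fixed-width MLP. Classifier: one
hidden layer of 256, ReLU, dropout 0.1, softmax.

## Training and evaluation

Two stages. Stage 1 trains the temporal encoder and projections with the
combined contrastive loss (Adam, lr 1e-3, 30 epochs, batch 32). Stage 2
freezes the encoder — the frozen variant is the default, with
`freeze_encoders=False` for fully end-to-end optimization — and trains
attention + classifier with cross-entropy (Adam, lr 1e-4, 150 epochs).
With a frozen encoder the representations are computed once in eval mode
and reused, which keeps fine-tuning cheap. All randomness (initialization,
shuffling, dropout) derives from the config seed; identical seeds give
bit-identical loss curves. NaN losses abort with the offending term named.

Evaluation: accuracy and F1 from one-vs-rest confusion counts. The printed
F1 is binary; for 3–4 classes the package macro-averages the per-class
one-vs-rest F1, and a class with TP = FP = FN = 0 contributes 0 and is
flagged. Cross-validation is stratified and assigned at the *trial* level
(default; the unit matters because 50 %-overlapping blocks from one trial
share content — block-level folds would leak train data into test).
Fourfold is the default.

## Synthetic benchmark

The generator draws, per trial, a latent class vector (orthonormal class
centroids scaled by `class_separation = 2.0`, plus latent noise sd 0.25)
and renders three linked modality views: each modality's mixing map is the
nearest orthogonal matrix to a shared map plus a modality-specific
perturbation, offset by `modality_gap` (default 0.5) along mutually
orthogonal directions — so same-sample cross-modal similarity is high but
below 1 and decreases as the gap grows. Streams: video = per-frame noisy
projections of the view (16 fps, width 16); audio = eight
amplitude-modulated tones (200–4000 Hz, 16 kHz) whose loudness encodes the
view, so the log-Mel spectrogram recovers it; EEG = 8 channels at 128 Hz
of five band-centered oscillations whose amplitudes encode the view, so
band power recovers it. `silent_audio_frac` of trials get 1e-4-amplitude
Gaussian noise instead of tones (near-zero rather than exactly zero, to
exercise thresholding realistically). Default size: 4 classes × 10 trials
of 8 s → 120 blocks; this is deliberately desk-scale so the full two-stage
pipeline cross-validates in a few minutes on one CPU.

Passing on this benchmark shows the machinery is wired correctly — the
losses align and separate what they should, fusion and folds are leak-free,
the pipeline recovers a recoverable signal. It does **not** show
performance on real recordings: the generator has no EEG physiology
(evoked responses, artifacts, 1/f background), no natural video statistics,
no perceptually plausible audio, and its class signal is far cleaner than
human affect ratings.

## Numerical engine

The trainable components run on a small reverse-mode autodiff engine over
float64 numpy arrays included in the package (`mercl._tensor`, `mercl.nn`):
broadcasting arithmetic, batched matmul, reductions, shape/slice/pad ops,
the needed nonlinearities, and Adam. Gradients are verified against central
finite differences in the test suite. Everything is single-threaded
numpy — deterministic across runs on the same platform.

## Known limitations

* Spatial encoders ship as frozen reference projections; reproducing the
  feature quality of large pre-trained backbones is explicitly out of scope.
* The literal (unsoftened) ratio loss is exposed for study but cannot be
  used for stable training in general position; the batched trainer uses it
  only when every anchor's ratio is in-domain, and raises otherwise.
* Batch normalization in training mode couples time steps through the
  batch statistics; strict causality holds in eval mode.
* Lag correction is a fixed configured shift, not an estimator.
* The CV unit is the trial; subject-level splitting is supported only
  insofar as callers map one subject per trial grouping themselves.
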