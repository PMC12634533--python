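# Methods

## Model

The classifier treats a 4-s multichannel EEG window as a single-channel
image `X ∈ R^{H×W}` with one row per electrode (H = 19 by default, the 10–20
montage without ECG) and one column per sample (W = 4 s × sampling rate).
The first layer is a *fixed* bank of 3×3 Sobel kernels with coefficients
±0.1/±0.2 — deliberately not the classic ±1/±2 scaling. The horizontal
kernel `Gx` responds to change along the time axis, the vertical kernel
`Gy = Gxᵀ` to change across adjacent electrode rows. The pair is replicated
`nf` times and concatenated, so the bank exposes `2·nf` output channels in
the fixed order Gx, Gy, Gx, Gy, …; with the default `nf = 10` the gradient
map has 20 channels. The replicated channels are exact copies — the
replication buys the downstream convolution more input channels, not more
information — and the package's filter-count sweep confirms accuracy does
not depend on it.

The layer is applied as stride-1, zero-padded SAME cross-correlation (the
deep-learning convention: no kernel flip). Zero padding means the one-pixel
border responds to the artificial data/zero edge; every interior location of
a constant input maps to zero because each kernel's coefficients sum to
zero. For multi-feature-channel inputs the kernels act per feature channel
and sum, the standard convolution contract; the default pipeline always has
one feature channel.

Then: 20 valid-mode 2×9 filters with ReLU → `(H−1)×(W−8)×20`; 18 valid-mode
8×7 filters with no activation → `(H−8)×(W−14)×18`; flatten to
`Df = (H−8)(W−14)·18`; dense 350 with **sigmoid** (unusual but intentional);
dense 60 purely linear; dense 1 with sigmoid. Convolutions carry no biases;
dense layers do. The network returns both the score and the Sobel map so the
robustness harness can measure the layer's effect on signal quality from the
same forward pass.

By default the Sobel kernels are frozen; `backward(..., trainable_sobel=True)`
also returns kernel gradients for experiments that fine-tune the bank from
its Sobel initialisation.

## Training

- Loss: plain MSE between the 0/1 label and the sigmoid score (not
  cross-entropy — part of the architecture's definition here).
- Optimiser: SGD with momentum, `η = 0.01`, `γ = 0.9`. The classical
  recurrence is `v ← γv + ηg`, `θ ← θ − v`; with the default Nesterov
  variant the step becomes `θ ← θ − (γv′ + ηg)` after `v′ ← γv + ηg`,
  the standard look-ahead reparameterisation.
- Inverted dropout with `p = 0.03` on the raw input only, never at
  inference.
- Initialisation: Glorot-uniform, seeded (a sensible default for a
  sigmoid-heavy head); biases zero. Parameters are float32; gradients are
  verified in float64 against central differences.
- Preprocessing: each epoch image is z-scored (one mean/std over the whole
  image). Microvolt-scale raw inputs saturate the sigmoid head under MSE;
  per-epoch standardisation removes the amplitude scale while preserving
  the spatial contrasts the classifier should use. It is applied
  identically at train and test time.
- Splits are **subject-wise** and stratified (default 70/15/15): all epochs
  of a recording stay in one partition, eliminating within-subject leakage.
  An epoch-wise mode exists for comparability experiments but is documented
  as leakage-prone. Classification threshold is 0.5 with MDD positive; a
  score of exactly 0.5 counts as HC. Sensitivity/specificity/accuracy come
  from explicit confusion counts, and any zero denominator yields NaN
  rather than a silent 0.
- Defaults batch 64 / 40 training epochs are configurable; the desk study
  below uses smaller values because its task saturates almost immediately.

## Synthetic EEG

Each channel is the sum of a 1/f^(exponent) Gaussian background
(spectrally shaped white noise, exponent 1.0 by default) and three
random-frequency, random-phase sinusoids per rhythm band — delta 1–4,
theta 4–8, alpha 8–13, beta 13–30 Hz — with relative amplitudes
√(band power), default powers 1.0/0.6/1.2/0.4. Amplitudes are scaled to
tens of microvolts. Bands whose range lies above 0.45× the sampling rate
are skipped.

The class effect emulates frontal alpha asymmetry: in class 1 the alpha
amplitude is multiplied by `(1 + effect_size)` on Fp1/F3/F7 and divided by
it on Fp2/F4/F8. `effect_size = 0` makes the classes statistically
identical (verified by a two-sample test on the asymmetry index);
`effect_size = 3` makes them trivially separable. Everything derives from
one seed (per-subject seeds are spawned from the dataset seed), and a flag
can append a crude synthetic ECG row for 20-row experiments.

What the generator does *not* emulate: real artifacts (EMG/EOG/movement),
inter-subject montage variability, non-stationarity beyond random phases,
and connectivity-based class effects. Passing the end-to-end tests
therefore shows the pipeline can recover a planted, amplitude-coded class
difference — not that it reaches any particular accuracy on clinical EEG.

## Robustness harness

White Gaussian noise is rescaled exactly to each nominal input SNR
(20, 15, 10, 5, 0, −5 dB by default) per epoch. Input-side quality compares
noisy vs clean epochs; output-side quality compares Sobel(noisy) vs
Sobel(clean) — the only reference that makes "improvement" well defined for
a gradient operator whose output is not in the input's units. Deltas are
output minus input. SNR is `10·log10(P_ref / P_residual)`; PSNR uses the
reference's max−min range as peak; SSIM uses the standard 11×11 Gaussian
window, σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range from the reference
(delegated to scikit-image and cross-checked against a direct windowed
oracle in the tests). Identical signals yield an explicit infinite-dB
sentinel, never a silent average. Metrics are computed per epoch image
(SSIM per distinct gradient channel) and averaged over epochs; accuracy is
measured on re-standardised noisy epochs, matching the deployment
preprocessing. A `transform` hook swaps the Sobel layer for any map — the
identity transform is the plumbing control for which every delta is
exactly zero — and the noise model can likewise be replaced for pink/EMG
extensions.

Because the Sobel layer is linear and the injected noise is white, the SNR
gain it confers is the difference between the filter's power gain on the
signal spectrum and on a flat spectrum — a constant, independent of noise
level. The sweep reproduces this flatness; the *sign and size* of the gain
depend on the signal's spectral shape, so values on synthetic EEG are not
comparable to any particular clinical recording.

## Desk-scale study conditions

The reference study (`sobelnet.study`, also run by
`scripts/acceptance.py`) uses 8 MDD + 8 HC subjects, 60-s recordings,
19 channels at 64 Hz (every rhythm band stays below Nyquist), effect size
3.0, non-overlapping 4-s windows (240 epochs of 19×256), subject-wise
6/1/1 + 6/1/1 split, batch 32, 8 training epochs (the task saturates in
1–2), and a 6-epoch schedule for the nf ∈ {10, 20, 30} sweep. The
shuffled-label control permutes epoch labels and segments the held-out
subjects with a 0.5-s stride: accuracy against labels that are independent
of the signal is a mean of i.i.d. coin flips, so the denser stride tightens
the estimate around 0.5 (±0.1 is ≈ 3 binomial standard errors at n ≈ 230).

## Numerical choices and edge cases

- Convolutions run as im2col + BLAS matmul, chunked over the batch so no
  patch buffer exceeds ~64 MB; the backward input gradient is a full
  cross-correlation with the flipped kernel.
- "Exactly zero" claims (constant-input annihilation, identity-control
  deltas) hold to double-precision rounding of paired ± terms (~1e-16);
  tests assert < 1e-12.
- Valid convolutions require H ≥ 9 and W ≥ 15; errors name the minimum.
  SSIM requires maps at least 11×11. A window longer than its recording
  yields zero epochs, documented, not an error.
- EDF export quantises to 16 bits over each channel's physical range
  (1-s records, integer sampling rates); round-trips are exact to that
  quantisation. Truncated files fail loudly at parse time.
- Checkpoints are HDF5 with a schema_version; round-trips are bit-exact.

## Known limitations

- The dense head is enormous at full scale (350 × Df ≈ 70 M parameters for
  19×1024 inputs); the study runs at 64 Hz to keep desk runs on one CPU in
  minutes. Full-scale training is supported but slow in pure numpy.
- Clinical headline metrics require the original patient dataset and are
  out of scope here; the synthetic study validates mechanism, not clinical
  performance.
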