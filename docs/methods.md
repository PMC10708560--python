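# Methods

## Signal model

A continuous-wave (CW) Doppler radar at carrier frequency f = 24 GHz
(wavelength λ = c/f ≈ 12.49 mm) illuminates a seated subject at standoff
distance d₀ ∈ [0.6, 1] m. The chest wall moves as

    x(t) = a_r cos(2π F_r t + φ_r) + a_c cos(2π F_c t + φ_c) + x_m(t),

where F_r ∈ [0.16, 0.33] Hz and F_c ∈ [0.83, 2] Hz are the respiratory and
cardiac rates of a resting adult, a_r ∈ [4, 12] mm and a_c ∈ [0.2, 0.5] mm
the corresponding displacement amplitudes, and x_m an optional random-walk
body-motion term (off by default). After quadrature demodulation the complex
baseband is a pure phase modulation,

    B(t) = A_b s(t) · exp[j β_r cos(2π F_r t + φ_r)]
                    · exp[j β_c cos(2π F_c t + φ_c)] + N(t),

with A_b = A e^{j4πd₀/λ} (A fixed to 1), s(t) the body-motion/phase-drift
phasor (identity by default), and N(t) circularly symmetric complex Gaussian
noise. Two modulation conventions are implemented:

* `physical` (default): β = 4πa/λ, the phase deviation implied by the
  two-way path-length change — β_r ≈ 4–12 rad, β_c ≈ 0.2–0.5 rad;
* `paper_literal`: β_r = β_c = 1, a simplified unit-index variant kept for
  exact replication of the bare-exponent formulation.

Useful consequences, all verified by the test suite: the noiseless envelope
is constant (|B| ≡ A); a single modulation tone produces spectral lines at
harmonics k·F with magnitudes |J_k(β)| (Jacobi–Anger expansion); the
unwrapped baseband angle is exactly β_r cos(2πF_r t+φ_r) + β_c cos(2πF_c t+φ_c)
plus a constant, so an FFT peak search on the detrended angle recovers both
rates to the 1/T ≈ 0.02 Hz grid. That spectral estimator
(`estimate_rates_fft`, Hann window, per-band peak with quadratic
interpolation, and a guard band excluding the respiration line when searching
for the much weaker heart line) is the package's non-neural oracle: it closes
the loop between the generator and its labels but plays no role in training.

Noise is calibrated against the mean squared magnitude of the noiseless
record: SNR(dB) = 10 log₁₀(P_signal/P_noise), variance split equally between
I and Q. Requested and measured SNR agree within 0.05 dB averaged over 100
seeds.

## Synthetic corpora

Each corpus draws per-subject (F_c, F_r) pairs uniformly from the state
bands and observes every subject across an equally spaced SNR grid spanning
[−10, 10] dB ("environments"); initial phases and d₀ are randomized per
record, amplitudes per subject. The class bands are:

| state      | F_c (Hz)     | F_r (Hz)     |
|------------|--------------|--------------|
| drowsiness | [0.55, 0.83) | [0.10, 0.16) |
| normal     | [0.83, 2.0]  | [0.16, 0.33] |
| stress     | (2.0, 2.5]   | (0.33, 0.50] |

The out-of-range margins (bradycardia/bradypnea-like below, tachycardia-like
above) are configurable; only "below"/"above the normal range" is specified
by the underlying study design, so the widths are this package's choice.

At full scale the three corpora are 30×100 = 3000 regression records,
(20+16+17)×100 = 5300 classification records, and 5-per-state ×3×100 = 1500
generalization records (unseen subjects carrying both label types, used only
for evaluation). Splits are 64/16/20 train/val/test by seeded shuffle
(shuffle seed 4), stratified by class for classification. All builders are
pure functions of (parameters, seed).

`resample_and_segment` provides the generic ingestion path for externally
recorded I/Q streams: rational anti-aliased resampling
(`scipy.signal.resample_poly`) to the working rate followed by
non-overlapping fixed-length windows, dropping the remainder.

## Model families

All four families share the skeleton: temporal feature extractor → pooling →
dense head (widths 64, 32, ReLU, dropout 0.3) → 2 linear outputs (F_c, F_r)
or 3-way softmax. Inputs are the I and Q channels, z-scored per record
(an unwrapped-angle single-channel mode is also available). Full-scale
extractors:

* **1D-CNN** — two 128-filter, 512-tap convolutions, each conv→BN→ReLU→
  max-pool (size 4), then flatten (without the normalization, the
  regression-rate Adam step drives the flatten head into a dead,
  mean-predicting regime);
* **TCN** — six residual blocks of dilated causal convolutions (kernel 3,
  dilations 1…32 → 253-sample receptive field), each block conv→BN→ReLU→
  dropout twice plus a 1×1-projected residual; global average pooling.
  Dropout inside the blocks (`tcn_block_dropout`) is kept light and is
  separate from the head dropout: twelve 0.3-dropout layers at the
  classification learning rate stall optimization for tens of epochs;
* **Bi-LSTM** — two bidirectional 128-unit LSTM layers with a normalization
  layer between, global average pooling;
* **CRNN** — one 512-tap convolution (BN, ReLU, max-pool) feeding a
  128-unit bidirectional LSTM, global average pooling.

Convolution stride is a free parameter (`conv_stride`): the filters always
see the full-rate input, the stride only decimates the feature maps, which
is how the desk scale halves downstream cost without resampling the data.
Where the TCN and the stand-alone Bi-LSTM decimate their input directly
(`tcn_pool`, `lstm_pool`), the decimator is a fixed Kaiser-window FIR
lowpass (cutoff 0.8 of the decimated Nyquist) rather than a boxcar average:
the boxcar's sinc response attenuates the top of the cardiac band to ~0.64
amplitude, which measurably costs classification accuracy. Input encodings:
`iq` (default, 2 z-scored channels), `phase` (unwrapped detrended angle,
1 channel), and `iq_phase` (all three). The phase channel makes the rates
directly visible at high SNR but collapses into an unwrappable random walk
at negative SNR, so the coherent `iq` default wins overall — both
alternatives were evaluated and kept as options.

Parameter budgets at these defaults order CNN (11.1 M) > TCN (558 k) >
Bi-LSTM (548 k) > CRNN (414 k), and the classification and regression
variants of each family differ by exactly head_width+1 = 33 parameters (the
one extra output unit). Exact replication of any particular published totals
is a non-goal; head shapes, pool sizes and normalization placement are
configurable and under-determined by the architecture descriptions.

The layers run on a compact numpy engine written for this package
(`vitalradar.nn`): explicit forward/backward passes, FFT-domain convolution
for long kernels and a slice-gather path for short (dilated) ones, full
backpropagation through time for the LSTM, inverted dropout, batch
normalization with running statistics, and Adam. Every backward pass is
verified against central finite differences in float64; float32 is the
working precision. The short-kernel path is used for all dilated
convolutions because it is numerically exactly causal (the FFT path spreads
~1e-7 rounding noise across time, which matters only to causality probes).

## Training protocol

Adam, batch size 64, fixed epoch count (60 at full scale), no early stopping
and no schedule; learning rate 0.001 with an RMSE loss for regression and
0.0001 with categorical cross-entropy for classification. Regression targets
are standardized per output on the train split (inverted at prediction):
with raw Hz targets the loss is dominated by the ~7×-wider F_c range and the
F_r gradient starves — desk-scale runs without scaling learned F_c only.

`TrainConfig.tail_average_epochs` optionally averages the last k epochs'
weights for evaluation (a cheap stabilizer of fixed-epoch training); the
default (0) keeps the protocol's final-epoch weights and all presets leave
it off.

Evaluation reports RMSE, MAE and R² per target for regression; accuracy,
macro precision/recall/F1 and the 3×3 confusion matrix for classification.
Desk-scale parameter-recovery checks score held-out records from the clean
end of the noise sweep (0 dB and up): at one fifth of the full-scale record
length the strongly negative-SNR records are dominated by irreducible noise,
and the recovery question — does the trained model read the rates out of a
resolvable record? — is posed where the information exists. Full-sweep test
metrics are what the repeated-evaluation reports and the benchmark script
publish.
`repeated_evaluation` retrains with derived seeds and reports mean ± standard
deviation over repeats (repeat-level std). For blocks of records sharing one
true label (the generalization corpus: 100 records per subject differing
only in SNR), between-record variance is zero and R² is undefined; the
adapted statistic R2* = 1 − Σ(y−ŷ)²/Σy² is used instead, reported in percent
per state and target.

## Problem scales

Three named scales configure record geometry, corpus sizes, model widths and
epochs together:

| scale | record | corpora (reg/clf/gen) | conv kernel/filters/stride | TCN | LSTM | epochs |
|-------|--------|--------------------|--------------------|-----|------|--------|
| full  | 5001 @ 100 Hz | 3000 / 5300 / 1500 | 512 / 128 / 1 | 128 ch | 128 | 60 |
| desk  | 1001 @ 20 Hz  | 1020 / 1484 / 510  | 201 / 64 / 2  | 48 ch, ÷4 decim. | 64 (48 in CRNN), ÷4 decim. | 60 clf / 40 reg |
| tiny  | 201 @ 20 Hz   | smoke sizes        | 33 / 8 / 1    | 8 ch | 8 | 2 |

Desk dropout is task-dependent: the convolutional regression models train
underfit at the fixed epoch counts and carry 0.1; the classifiers and the
stand-alone Bi-LSTM (which do overfit) keep 0.3.

The desk scale keeps the 50 s observation window (hence the 0.02 Hz
resolution) and the full subject counts, and reduces the sampling rate and
the number of SNR environments; it is sized for a single CPU. A 10 Hz desk
variant was evaluated and rejected: halving the samples per record halves
the coherent integration gain and costs several accuracy points at low SNR,
an intrinsic loss no model choice recovers. The longer desk kernel
(201 taps = 10 s versus the full scale's 5.12 s) partly compensates the
already-halved integration by widening each filter's coherent window. Because a desk
record integrates 5× fewer samples, its low-SNR records are intrinsically
harder than full-scale ones: desk-scale errors concentrate below ≈ −4 dB
SNR, and desk accuracies should be read as lower bounds on what the same
pipeline attains at full scale. The `tiny` scale exists only to exercise
plumbing in seconds.

## Numerical and design choices

* Time axis starts at t = 0 with spacing 1/f_s; 5001 samples span 50.00 s.
* Initial phases φ_r, φ_c are nuisance parameters drawn uniform [0, 2π) per
  record; d₀ per record; amplitudes per subject.
* The SNR grid is deterministic (linspace inclusive of both endpoints);
  environments differ additionally in phases and d₀ but SNR is the only
  labeled environmental variable.
* Splits use largest-remainder rounding so fractions are met exactly
  (3000 → 1920/480/600; stratified per class within ±1 record).
* The normal-state F_c band follows the generation range [0.83, 2] Hz rather
  than the clinical resting range [0.83, 1.67] Hz; both appear in the source
  material, the generation range is what the corpora use.
* BatchNorm at inference uses running statistics (pointwise affine), so the
  TCN causality property holds exactly in evaluation mode.
* Degenerate metric inputs are flagged, not silently averaged: zero-variance
  truth → R² = NaN; absent class → NaN recall excluded from macro averages;
  Σy² = 0 → R2* raises.

## What the generator does and does not emulate

The simulator reproduces the phase-modulation physics, amplitude/rate
ranges, and the SNR sweep of the study design. It does not emulate real
radar artifacts: harmonically rich (non-sinusoidal) chest motion, sensor
phase noise and DC offsets, clutter and multipath, intermittent large body
movements, or inter-beat variability; all records are strictly stationary
within the 50 s window. Passing tests therefore demonstrate that the
pipeline learns the stated simulated conditions, not clinical performance.

## Known limitations

* Pure-numpy training is single-process and CPU-bound; full-scale
  reproduction (60 epochs, 10 repeats, all families) is hours of CPU time
  and is exposed via `vitalradar reproduce --scale full` rather than run in
  tests.
* The desk scale's low-SNR regime is harder than full scale (see above), so
  desk metrics undershoot the full-scale reference values by several points.
* Dense-head shapes are not tuned; no data augmentation; no early stopping
  (by protocol).
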