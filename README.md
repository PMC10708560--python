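# vitalradar

Contactless vital-sign monitoring with a 24 GHz continuous-wave (CW) Doppler
radar, for researchers studying driver physiological state: the package
simulates the radar's complex baseband return from chest motion, builds
labeled synthetic corpora across noise environments, and trains four
temporal neural-network families to (i) regress heart and respiration rates
and (ii) classify the subject's state as drowsiness, normal or stress.

## The model

Chest displacement from respiration and heartbeat,
x(t) = a_r cos(2πF_r t + φ_r) + a_c cos(2πF_c t + φ_c), phase-modulates the
radar echo; after quadrature demodulation the baseband is

    B(t) = A_b s(t) · e^{jβ_r cos(2πF_r t + φ_r)} · e^{jβ_c cos(2πF_c t + φ_c)} + N(t),

with modulation indices β = 4πa/λ, constant standoff phasor
A_b = e^{j4πd₀/λ}, and complex Gaussian noise N(t) at a prescribed SNR.
Records are 50 s I/Q acquisitions labeled with (F_c, F_r) in Hz or with one
of three physiological states (rates below / inside / above the normal
ranges F_c ∈ [0.83, 2] Hz, F_r ∈ [0.16, 0.33] Hz). Each simulated subject is
observed across an SNR sweep from −10 to 10 dB ("environments").

Four architectures — 1D-CNN, temporal convolutional network (TCN, dilated
causal convolutions), bidirectional LSTM, and a convolutional-recurrent
hybrid (CRNN) — share a common skeleton and are trained with Adam for a
fixed number of epochs (RMSE loss at lr 0.001 for regression;
cross-entropy at lr 0.0001 for classification; batch 64). Evaluation
reports RMSE / MAE / R² per rate, accuracy / precision / recall / F1 with
confusion matrices, and — for blocks of records that share a single true
label, where ordinary R² is undefined — the adapted statistic
R2\* = 1 − Σ(y−ŷ)²/Σy². Everything runs on a compact numpy neural-network
engine included in the package (gradient-checked conv/LSTM layers; no GPU
needed). See `docs/methods.md` for assumptions, scales and limitations.

## Worked example

```python
import numpy as np
from vitalradar import (VitalSignParameters, RadarConfig,
                        synthesize_baseband, estimate_rates_fft)

p = VitalSignParameters(fc_hz=1.30, fr_hz=0.25, ac_m=4e-4, ar_m=8e-3)
rec = synthesize_baseband(p, RadarConfig(), snr_db=5.0, seed=7)
fr_est, fc_est = estimate_rates_fft(rec)
print(f"respiration {fr_est:.3f} Hz, heart {fc_est:.3f} Hz")
```

prints

    respiration 0.250 Hz, heart 1.298 Hz

— the spectral-peak oracle recovers both rates of the 5 dB record on the
0.02 Hz grid of the 50 s window (the heartbeat line is ~20–60× weaker than
the respiration line, hence the guard band in the estimator). An end-to-end
desk-scale experiment (data → split → train → evaluate, a few CPU-minutes):

```python
from vitalradar import ExperimentConfig, run_experiment

cfg = ExperimentConfig(family="crnn", task="classification", scale="desk",
                       seed=0, out_dir="runs/demo")
result = run_experiment(cfg)
```

which logs

    [vitalradar] dataset: 1484 records (classification, scale=desk)
    [vitalradar] trained crnn for 60 epochs (333.125s)
    [vitalradar] test metrics: {'accuracy': 0.8412, 'precision': 0.8497, 'recall': 0.8403, 'f1': 0.8438}

(desk-scale accuracies for this model vary roughly 0.84-0.93 with the
corpus and training seeds; the run directory holds the config, manifest,
loss history, confusion matrix and weights). The same
pipeline at `scale="full"` reproduces the study-scale corpora
(3000 / 5300 / 1500 records of 5001 samples at 100 Hz) and the full-width
models — hours of CPU; `vitalradar reproduce --scale full` emits the
regression / classification / generalization result tables for all four
families.

The CLI mirrors the library: `vitalradar simulate | build-data | train |
evaluate | run | reproduce --help`.

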