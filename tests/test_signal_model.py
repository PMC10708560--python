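"""Radar baseband simulator: displacement, modulation, noise, rate recovery."""

import numpy as np
import pytest
from scipy.special import jv

from vitalradar import (
    BodyMotionSpec,
    RadarConfig,
    VitalSignParameters,
    add_noise,
    chest_displacement,
    estimate_rates_fft,
    synthesize_baseband,
)
from vitalradar.signal_model import modulation_indices


class TestChestDisplacement:
    def test_zero_amplitudes_give_zero_motion(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2, ac_m=0.0, ar_m=0.0)
        t = np.arange(0, 10, 0.01)
        assert np.all(chest_displacement(p, t) == 0.0)

    def test_cosine_peak_and_quarter_period(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2, ac_m=0.0, ar_m=0.010)
        x = chest_displacement(p, np.array([0.0, 1.25]))
        assert x[0] == pytest.approx(0.010, abs=1e-15)
        assert x[1] == pytest.approx(0.0, abs=1e-12)  # quarter period of 0.2 Hz

    def test_amplitude_bound_over_dense_grid(self):
        # brute-force evaluation: |x| can never exceed ar + ac = 8.4 mm
        p = VitalSignParameters(fc_hz=1.2, fr_hz=0.25, ac_m=4e-4, ar_m=8e-3)
        t = np.arange(0, 50, 0.01)
        x = chest_displacement(p, t)
        assert np.max(np.abs(x)) <= 8.4e-3 + 1e-15
        assert np.min(x) >= -8.4e-3 - 1e-15

    @pytest.mark.parametrize("kwargs", [
        dict(fc_hz=-1.0, fr_hz=0.2),
        dict(fc_hz=1.0, fr_hz=np.nan),
        dict(fc_hz=1.0, fr_hz=0.2, ac_m=-1e-4),
        dict(fc_hz=1.0, fr_hz=0.2, ar_m=-1e-3),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VitalSignParameters(**kwargs)

    def test_nonuniform_times_rejected(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2)
        with pytest.raises(ValueError):
            chest_displacement(p, np.array([0.0, 0.1, 0.3]))

    def test_random_walk_motion_is_cumulative_and_seeded(self):
        spec = BodyMotionSpec(kind="random_walk", step_std_m=1e-4)
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2, body_motion=spec)
        t = np.arange(0, 5, 0.05)
        x1 = chest_displacement(p, t, rng=7)
        x2 = chest_displacement(p, t, rng=7)
        assert np.array_equal(x1, x2)
        assert not np.allclose(x1, chest_displacement(p, t, rng=8))


class TestSynthesizeBaseband:
    def test_no_displacement_means_constant_phasor(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2, ac_m=0.0, ar_m=0.0)
        cfg = RadarConfig(n_samples=500)
        rec = synthesize_baseband(p, cfg, seed=0)
        ab = np.exp(1j * 4 * np.pi * cfg.d0_m / cfg.wavelength_m)
        assert np.allclose(rec.iq, ab)
        assert np.allclose(np.abs(rec.iq), 1.0)

    def test_constant_modulus_without_noise(self):
        p = VitalSignParameters(fc_hz=1.4, fr_hz=0.3)
        rec = synthesize_baseband(p, RadarConfig(), seed=3)
        mag = np.abs(rec.iq)
        assert mag.max() - mag.min() < 1e-9

    def test_physical_modulation_index_value(self):
        # 4*pi*ar/lambda with ar = 6 mm at 24 GHz (lambda = 12.49 mm)
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2, ar_m=6e-3)
        cfg = RadarConfig()
        beta_r, _ = modulation_indices(p, cfg)
        assert beta_r == pytest.approx(4 * np.pi * 6e-3 / cfg.wavelength_m)
        assert beta_r == pytest.approx(6.036, abs=2e-3)

    def test_paper_literal_mode_is_unit_index_phase_modulation(self):
        p = VitalSignParameters(fc_hz=1.3, fr_hz=0.22, phase_c_rad=0.0,
                                phase_r_rad=0.0)
        cfg = RadarConfig(n_samples=300, modulation_mode="paper_literal")
        rec = synthesize_baseband(p, cfg, seed=0)
        t = cfg.times()
        rng = np.random.default_rng(0)
        ab = np.exp(1j * 4 * np.pi * cfg.d0_m / cfg.wavelength_m)
        for idx in rng.integers(0, cfg.n_samples, size=10):
            expected = ab * np.exp(1j * np.cos(2 * np.pi * p.fr_hz * t[idx])) \
                          * np.exp(1j * np.cos(2 * np.pi * p.fc_hz * t[idx]))
            assert rec.iq[idx] == pytest.approx(expected, abs=1e-12)

    def test_bessel_line_spectrum_of_single_tone(self):
        # Jacobi-Anger: |DFT line at k*fr| of exp(j*beta*cos(2*pi*fr*t))
        # equals |J_k(beta)| when fr sits on the DFT grid.
        fs, n = 100.0, 5000
        cfg = RadarConfig(fs_hz=fs, n_samples=n)
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.26, ac_m=0.0, ar_m=6e-3,
                                phase_r_rad=0.0)
        beta, _ = modulation_indices(p, cfg)
        rec = synthesize_baseband(p, cfg, seed=0)
        spec = np.fft.fft(rec.iq) / n
        freqs = np.fft.fftfreq(n, 1 / fs)
        for k in range(6):
            line = np.abs(spec[np.argmin(np.abs(freqs - k * p.fr_hz))])
            assert line == pytest.approx(abs(jv(k, beta)), rel=0.02)

    def test_seeded_records_are_bit_identical(self):
        p = VitalSignParameters(fc_hz=1.1, fr_hz=0.28)
        r1 = synthesize_baseband(p, RadarConfig(n_samples=400), snr_db=3.0, seed=11)
        r2 = synthesize_baseband(p, RadarConfig(n_samples=400), snr_db=3.0, seed=11)
        assert np.array_equal(r1.iq, r2.iq)

    def test_invalid_snr_rejected(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2)
        with pytest.raises(ValueError):
            synthesize_baseband(p, RadarConfig(n_samples=10), snr_db=np.nan)


class TestAddNoise:
    def test_noiseless_path_bypasses_noise(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.2)
        cfg = RadarConfig(n_samples=256)
        rec_inf = synthesize_baseband(p, cfg, snr_db=np.inf, seed=5)
        rec_inf2 = synthesize_baseband(p, cfg, seed=5)
        assert np.array_equal(rec_inf.iq, rec_inf2.iq)
        assert np.abs(np.abs(rec_inf.iq) - 1).max() < 1e-12

    @pytest.mark.parametrize("snr_db,expected_ratio", [(0.0, 1.0), (-10.0, 10.0)])
    def test_noise_power_matches_request(self, snr_db, expected_ratio):
        # Monte-Carlo over 100 seeds on a unit-power input
        x = np.exp(1j * np.linspace(0, 20, 5001))
        powers = []
        for seed in range(100):
            noisy = add_noise(x, snr_db, np.random.default_rng(seed))
            powers.append(np.mean(np.abs(noisy - x) ** 2))
        assert np.mean(powers) == pytest.approx(expected_ratio, rel=0.1)

    def test_snr_calibration_within_half_db(self):
        p = VitalSignParameters(fc_hz=1.4, fr_hz=0.3)
        cfg = RadarConfig()
        measured = []
        for seed in range(100):
            clean = synthesize_baseband(p, cfg, seed=seed)
            noisy = synthesize_baseband(p, cfg, snr_db=5.0, seed=seed)
            n_pow = np.mean(np.abs(noisy.iq - clean.iq) ** 2)
            measured.append(10 * np.log10(np.mean(np.abs(clean.iq) ** 2) / n_pow))
        assert abs(np.mean(measured) - 5.0) < 0.5

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(16, dtype=complex), 0.0, np.random.default_rng(0))

    def test_infinite_snr_rejected_here(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(8, dtype=complex), np.inf, np.random.default_rng(0))


class TestEstimateRatesFFT:
    def test_single_tone_peak(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.25, ac_m=0.0)
        rec = synthesize_baseband(p, RadarConfig(), seed=0)
        fr_est, _ = estimate_rates_fft(rec)
        assert fr_est == pytest.approx(0.25, abs=0.02)

    def test_two_tone_recovery(self):
        p = VitalSignParameters(fc_hz=1.5, fr_hz=0.20, phase_c_rad=0.4,
                                phase_r_rad=1.1)
        rec = synthesize_baseband(p, RadarConfig(), seed=0)
        fr_est, fc_est = estimate_rates_fft(rec)
        assert fr_est == pytest.approx(0.20, abs=0.02)
        assert fc_est == pytest.approx(1.50, abs=0.02)

    def test_noisy_recovery_rate_at_10db(self):
        rng = np.random.default_rng(99)
        hits = 0
        for seed in range(50):
            fr = rng.uniform(0.16, 0.33)
            fc = rng.uniform(0.83, 2.0)
            p = VitalSignParameters(
                fc_hz=fc, fr_hz=fr,
                phase_c_rad=rng.uniform(0, 2 * np.pi),
                phase_r_rad=rng.uniform(0, 2 * np.pi),
            )
            rec = synthesize_baseband(p, RadarConfig(), snr_db=10.0, seed=seed)
            fr_est, _ = estimate_rates_fft(rec)
            hits += abs(fr_est - fr) <= 0.02
        assert hits >= 45  # >= 90% of 50 seeds

    def test_empty_band_rejected(self):
        p = VitalSignParameters(fc_hz=1.0, fr_hz=0.25)
        rec = synthesize_baseband(p, RadarConfig(n_samples=8, fs_hz=100.0), seed=0)
        with pytest.raises(ValueError):
            estimate_rates_fft(rec, fr_band=(0.101, 0.102), fc_band=(1.0, 2.0))
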