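"""Complex-baseband model of a CW Doppler radar observing chest motion.

A continuous-wave radar transmits an unmodulated carrier; reflection off the
chest wall phase-modulates the echo by ``4*pi*x(t)/lambda`` radians, where
``x(t)`` is the chest displacement produced by respiration and heartbeat.
Quadrature demodulation yields the complex baseband signal

    B(t) = Ab * s(t) * exp(j*beta_r*cos(2*pi*Fr*t + phi_r))
                     * exp(j*beta_c*cos(2*pi*Fc*t + phi_c)) + N(t)

with modulation indices ``beta = 4*pi*a/lambda`` (``physical`` mode) or
``beta = 1`` (``paper_literal`` mode, the bare-exponent variant), a constant
standoff phasor ``Ab = A*exp(j*4*pi*d0/lambda)``, an optional slow body-motion
term ``s(t)``, and circularly symmetric complex Gaussian noise ``N(t)`` at a
prescribed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.fft
import scipy.signal

__all__ = [
    "SPEED_OF_LIGHT",
    "BodyMotionSpec",
    "VitalSignParameters",
    "RadarConfig",
    "BasebandRecord",
    "chest_displacement",
    "body_motion_displacement",
    "synthesize_baseband",
    "add_noise",
    "estimate_rates_fft",
]

SPEED_OF_LIGHT = 299_792_458.0  # m/s


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class BodyMotionSpec:
    """Random body-movement component ``xm(t)``.

    ``kind="none"`` keeps the chest the only moving scatterer; ``random_walk``
    adds a Gaussian random walk with per-sample step ``step_std_m`` to emulate
    slow torso drift.
    """

    kind: str = "none"
    step_std_m: float = 0.0
    seed_offset: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "random_walk"):
            raise ValueError(f"unknown body-motion kind: {self.kind!r}")
        if not np.isfinite(self.step_std_m) or self.step_std_m < 0:
            raise ValueError("step_std_m must be finite and >= 0")


@dataclass(frozen=True)
class VitalSignParameters:
    """Ground-truth physiology of one simulated subject.

    Rates are in Hz (``fc_hz`` cardiac, ``fr_hz`` respiratory), displacement
    amplitudes in meters (typical heartbeat 0.2-0.5 mm, respiration 4-12 mm).
    Initial phases are nuisance parameters, uniform on [0, 2*pi) when records
    are drawn randomly.
    """

    fc_hz: float
    fr_hz: float
    ac_m: float = 3.5e-4
    ar_m: float = 8e-3
    phase_c_rad: float = 0.0
    phase_r_rad: float = 0.0
    body_motion: Optional[BodyMotionSpec] = None

    def __post_init__(self):
        for name in ("fc_hz", "fr_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("ac_m", "ar_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class RadarConfig:
    """Radar front-end and acquisition geometry.

    Defaults follow a 24 GHz CW sensor sampling the baseband at 100 Hz for
    5001 samples (a 50 s observation window, 0.02 Hz spectral resolution).
    ``modulation_mode`` selects the phase-deviation convention (see module
    docstring).
    """

    carrier_hz: float = 24e9
    d0_m: float = 0.8
    fs_hz: float = 100.0
    n_samples: int = 5001
    modulation_mode: str = "physical"

    def __post_init__(self):
        if self.carrier_hz <= 0 or self.fs_hz <= 0:
            raise ValueError("carrier_hz and fs_hz must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.modulation_mode not in ("physical", "paper_literal"):
            raise ValueError(f"unknown modulation_mode: {self.modulation_mode!r}")

    @property
    def wavelength_m(self) -> float:
        return SPEED_OF_LIGHT / self.carrier_hz

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs_hz

    def times(self) -> np.ndarray:
        """Uniform time axis starting at t=0 with spacing 1/fs."""
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class BasebandRecord:
    """One labeled complex baseband acquisition."""

    iq: np.ndarray
    fc_hz: float
    fr_hz: float
    snr_db: float = np.inf
    state: Optional[str] = None
    seed: Optional[int] = None
    config: RadarConfig = field(default_factory=RadarConfig)

    def __post_init__(self):
        self.iq = np.asarray(self.iq)
        if self.iq.ndim != 1:
            raise ValueError("iq must be one-dimensional")
        if len(self.iq) != self.config.n_samples:
            raise ValueError(
                f"iq length {len(self.iq)} != config.n_samples {self.config.n_samples}"
            )


def body_motion_displacement(
    spec: Optional[BodyMotionSpec], n: int, rng
) -> np.ndarray:
    """Sample the body-motion displacement ``xm`` (meters) on an n-point grid."""
    if spec is None or spec.kind == "none" or spec.step_std_m == 0.0:
        return np.zeros(n)
    rng = _as_rng(rng)
    steps = rng.normal(0.0, spec.step_std_m, size=n)
    steps[0] = 0.0
    return np.cumsum(steps)


def chest_displacement(
    params: VitalSignParameters, times: np.ndarray, rng=None
) -> np.ndarray:
    """Chest-wall displacement x(t) = xr(t) + xc(t) + xm(t) in meters.

    xr and xc are cosines at the respiratory and cardiac rates; xm follows
    ``params.body_motion`` (zero when unset).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if times.size > 1:
        dt = np.diff(times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced and increasing")
    xr = params.ar_m * np.cos(2 * np.pi * params.fr_hz * times + params.phase_r_rad)
    xc = params.ac_m * np.cos(2 * np.pi * params.fc_hz * times + params.phase_c_rad)
    xm = body_motion_displacement(params.body_motion, times.size, rng)
    return xr + xc + xm


def add_noise(iq: np.ndarray, snr_db: float, rng) -> np.ndarray:
    """Add circularly symmetric complex Gaussian noise at the requested SNR.

    Signal power is the mean squared magnitude of the (noiseless) input; the
    noise variance ``P/10^(snr/10)`` is split equally between the in-phase and
    quadrature components.
    """
    iq = np.asarray(iq)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite (use synthesize_baseband with "
                         "snr_db=inf for the noiseless path)")
    power = float(np.mean(np.abs(iq) ** 2))
    if power == 0.0:
        raise ValueError("SNR is undefined for an all-zero signal")
    rng = _as_rng(rng)
    sigma2 = power / 10.0 ** (snr_db / 10.0)
    scale = np.sqrt(sigma2 / 2.0)
    noise = rng.normal(0.0, scale, size=iq.shape) + 1j * rng.normal(
        0.0, scale, size=iq.shape
    )
    return iq + noise


def modulation_indices(params: VitalSignParameters, config: RadarConfig):
    """(beta_r, beta_c) phase-deviation amplitudes in radians."""
    if config.modulation_mode == "physical":
        lam = config.wavelength_m
        return 4 * np.pi * params.ar_m / lam, 4 * np.pi * params.ac_m / lam
    return 1.0, 1.0


def synthesize_baseband(
    params: VitalSignParameters,
    config: RadarConfig = RadarConfig(),
    snr_db: float = np.inf,
    rng=None,
    state: Optional[str] = None,
    seed: Optional[int] = None,
) -> BasebandRecord:
    """Synthesize one complex baseband record.

    The noiseless core is a pure phase modulation (constant modulus):
    ``Ab * s(t) * exp(j*beta_r*cos(2*pi*Fr*t + phi_r)) *
    exp(j*beta_c*cos(2*pi*Fc*t + phi_c))`` with A fixed to 1. A finite
    ``snr_db`` routes the record through :func:`add_noise`.
    """
    if np.isnan(snr_db) or (np.isinf(snr_db) and snr_db < 0):
        raise ValueError("snr_db must be finite or +inf")
    if seed is not None and rng is None:
        rng = np.random.default_rng(seed)
    rng = _as_rng(rng)
    t = config.times()
    beta_r, beta_c = modulation_indices(params, config)
    lam = config.wavelength_m
    phase = beta_r * np.cos(
        2 * np.pi * params.fr_hz * t + params.phase_r_rad
    ) + beta_c * np.cos(2 * np.pi * params.fc_hz * t + params.phase_c_rad)
    xm = body_motion_displacement(params.body_motion, t.size, rng)
    ab = np.exp(1j * 4 * np.pi * config.d0_m / lam)
    iq = ab * np.exp(1j * (phase + 4 * np.pi * xm / lam))
    if np.isfinite(snr_db):
        iq = add_noise(iq, snr_db, rng)
    return BasebandRecord(
        iq=iq,
        fc_hz=params.fc_hz,
        fr_hz=params.fr_hz,
        snr_db=float(snr_db),
        state=state,
        seed=seed,
        config=config,
    )


def _band_peak(freqs, mag, lo, hi, exclude=None):
    mask = (freqs >= lo) & (freqs <= hi)
    if exclude is not None:
        lo_x, hi_x = exclude
        mask &= ~((freqs >= lo_x) & (freqs <= hi_x))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"frequency band [{lo}, {hi}] is empty after discretization")
    k = idx[np.argmax(mag[idx])]
    # quadratic interpolation of log-magnitude around the peak bin
    if 0 < k < len(mag) - 1 and mag[k - 1] > 0 and mag[k + 1] > 0 and mag[k] > 0:
        a, b, c = np.log(mag[k - 1]), np.log(mag[k]), np.log(mag[k + 1])
        denom = a - 2 * b + c
        if denom < 0:
            delta = 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(freqs[k] + delta * (freqs[1] - freqs[0]))
    return float(freqs[k])


def estimate_rates_fft(
    record: BasebandRecord,
    fr_band=(0.08, 0.52),
    fc_band=(0.52, 2.6),
    guard_hz: float = 0.1,
):
    """Spectral-peak rate estimator used as the non-neural validation oracle.

    The baseband angle is unwrapped, linearly detrended, Hann-windowed and
    Fourier-transformed; the respiratory rate is the peak within ``fr_band``
    and the cardiac rate the peak within ``fc_band`` after excluding a
    ``guard_hz`` neighborhood of the respiration line (which dominates the
    spectrum by one to two orders of magnitude). Returns ``(fr_est, fc_est)``.
    """
    iq = np.asarray(record.iq)
    if iq.size < 2:
        raise ValueError("record too short")
    fs = record.config.fs_hz
    for lo, hi in (fr_band, fc_band):
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band ({lo}, {hi}) outside (0, fs/2)")
    phase = np.unwrap(np.angle(iq))
    phase = scipy.signal.detrend(phase, type="linear")
    win = scipy.signal.get_window("hann", phase.size)
    spec = scipy.fft.rfft(phase * win)
    freqs = scipy.fft.rfftfreq(phase.size, d=1.0 / fs)
    mag = np.abs(spec)
    fr_est = _band_peak(freqs, mag, *fr_band)
    fc_est = _band_peak(
        freqs, mag, *fc_band, exclude=(fr_est - guard_hz, fr_est + guard_hz)
    )
    return fr_est, fc_est
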