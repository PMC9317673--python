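"""Synthetic two-wavelength PPG and accelerometer signal generator.

The generator produces RED/IR photoplethysmogram pairs with *known*
ground-truth heart rate, oxygen saturation and respiratory rate, so that
every downstream stage (filtering, beat detection, SpO2 calibration, the
FM/AM respiratory estimator, motion gating) can be validated without any
recorded human data.

Signal model
------------
Beats are laid down as a quasi-periodic pulse train.  The instantaneous
inter-beat interval is sinusoidally frequency-modulated at the respiratory
frequency (FM: heart rate speeds up on inspiration), and per-beat pulse
amplitudes are sinusoidally amplitude-modulated at the same frequency
(AM: stroke volume drops on inhalation).  Each beat uses an asymmetric
gamma-like template with a fast systolic rise and slow diastolic decay
and a single dominant maximum per beat.

Both channels share the same normalized pulsatile waveform; the RED
channel's perfusion (AC/DC fraction) is scaled so that the ratio-of-ratios
of the clean waveform equals the value the oximetry polynomial maps to the
requested SpO2.  Optional additive white noise and sinusoidal baseline
wander emulate sensor and physiological nuisance components, and samples
are clipped to an 18-bit ADC range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .oximetry import SPO2_MAX, ratio_from_spo2

ADC_BITS = 18
ADC_FULL_SCALE = 2**ADC_BITS - 1  # 262143 counts

# Pulse template: fraction of the beat interval at which the systolic
# peak occurs, and the sharpness of the gamma-like rise/decay.
_PULSE_PEAK_FRAC = 0.3
_PULSE_SHARPNESS = 3.0

#: Nominal gravity vector (device at rest, z axis up), in g.
GRAVITY_NOMINAL = np.array([0.0, 0.0, 1.0])


def invert_spo2_to_R(spo2_pct: float) -> float:
    """Ratio-of-ratios on the decreasing calibration branch for a target SpO2."""
    return ratio_from_spo2(spo2_pct)


@dataclass(frozen=True)
class SimParams:
    """Ground-truth physiology and nuisance parameters for one recording.

    Units: ``hr_bpm`` beats/min, ``rr_brpm`` breaths/min, ``spo2_pct``
    percent, depths are fractional (0-0.5), ``fs`` Hz, ``duration`` s,
    DC levels / noise / drift in ADC counts.
    """

    hr_bpm: float = 70.0
    rr_brpm: float = 15.0
    spo2_pct: float = 97.0
    fm_depth: float = 0.1
    am_depth: float = 0.1
    fs: float = 100.0
    duration: float = 30.0
    dc_red: float = 120_000.0
    dc_ir: float = 150_000.0
    perfusion_ir: float = 0.02
    noise_sd: float = 25.0
    drift_amp: float = 500.0
    drift_freq: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        if not 0 < self.hr_bpm <= 240:
            raise ValidationError("hr_bpm must lie in (0, 240]")
        if not 0 < self.rr_brpm < self.hr_bpm:
            raise ValidationError("rr_brpm must lie in (0, hr_bpm)")
        for name in ("fm_depth", "am_depth"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5]")
        if self.dc_red <= 0 or self.dc_ir <= 0:
            raise ValidationError("DC levels must be positive")
        if self.spo2_pct > SPO2_MAX:
            raise ValidationError(
                f"spo2_pct above calibration maximum {SPO2_MAX:.4f}"
            )
        if self.perfusion_ir <= 0:
            raise ValidationError("perfusion_ir must be positive")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ValidationError("noise_sd and drift_amp must be nonnegative")


@dataclass
class PPGRecording:
    """Two aligned uniform sample series (RED, IR) in ADC counts."""

    fs: float
    t0: float
    red: np.ndarray
    ir: np.ndarray

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.ir = np.asarray(self.ir, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.red.shape != self.ir.shape or self.red.ndim != 1 or len(self.red) < 1:
            raise ValidationError("red and ir must be equal-length 1-d series")
        for ch in (self.red, self.ir):
            if np.any(~np.isfinite(ch)) or ch.min() < 0 or ch.max() > ADC_FULL_SCALE:
                raise ValidationError("samples must be finite ADC counts in range")

    @property
    def n(self) -> int:
        return len(self.ir)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times relative to the recording start, seconds."""
        return np.arange(self.n) / self.fs


@dataclass
class AccelTrace:
    """Uniform 3-axis acceleration series in g, time-aligned to the PPG."""

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValidationError("axis series must have equal lengths")
        if any(np.any(~np.isfinite(a)) for a in (self.ax, self.ay, self.az)):
            raise ValidationError("acceleration samples must be finite")

    @property
    def n(self) -> int:
        return len(self.ax)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def samples(self) -> np.ndarray:
        """(n, 3) array of acceleration vectors in g."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class SensorResponseModel:
    """Idealized LED-drive -> ADC transfer of the optical front end.

    Mean output is ``clip(gain * level, 0, saturation_level)``; sampled
    output adds white noise of ``noise_sd`` counts.  Non-decreasing in the
    drive level by construction.
    """

    gain: float
    saturation_level: float = float(ADC_FULL_SCALE)
    noise_sd: float = 0.0

    def respond(self, level: float) -> float:
        """Noise-free mean ADC output at a drive level."""
        return float(np.clip(self.gain * level, 0.0, self.saturation_level))

    def sample(self, level: float, n: int, rng: np.random.Generator) -> np.ndarray:
        out = self.gain * level + rng.normal(0.0, self.noise_sd, size=n)
        return np.clip(out, 0.0, self.saturation_level)


def _pulse_template(phase: np.ndarray) -> np.ndarray:
    """Asymmetric gamma-like pulse on normalized beat phase in [0, 1).

    Rises to a single maximum of 1 at ``_PULSE_PEAK_FRAC`` then decays;
    value at phase 0 is exactly 0.
    """
    r = np.asarray(phase, dtype=float) / _PULSE_PEAK_FRAC
    return r**_PULSE_SHARPNESS * np.exp(_PULSE_SHARPNESS * (1.0 - r))


def _beat_onsets(params: SimParams) -> np.ndarray:
    """Beat onset times with sinusoidal FM of the instantaneous period."""
    d0 = 60.0 / params.hr_bpm
    f_resp = params.rr_brpm / 60.0
    onsets = [0.0]
    t = 0.0
    while t < params.duration + 2.0 * d0:
        d = d0 * (1.0 + params.fm_depth * math.sin(2.0 * math.pi * f_resp * t))
        t += d
        onsets.append(t)
    return np.asarray(onsets)


def generate_ppg(params: SimParams) -> PPGRecording:
    """Generate a two-channel PPG recording from ground-truth parameters.

    Deterministic given ``params.seed``.  The noiseless waveform's
    ratio-of-ratios equals ``invert_spo2_to_R(params.spo2_pct)`` by
    construction (both channels share one normalized pulse waveform).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs

    onsets = _beat_onsets(params)
    idx = np.searchsorted(onsets, t, side="right") - 1
    d = onsets[idx + 1] - onsets[idx]
    phase = (t - onsets[idx]) / d

    f_resp = params.rr_brpm / 60.0
    amp = 1.0 + params.am_depth * np.sin(2.0 * np.pi * f_resp * onsets[idx])
    pulsatile = amp * _pulse_template(phase)

    ratio = ratio_from_spo2(params.spo2_pct)
    ac_ir = params.perfusion_ir * params.dc_ir
    ac_red = ratio * params.perfusion_ir * params.dc_red

    drift = params.drift_amp * np.sin(2.0 * np.pi * params.drift_freq * t)
    ir = params.dc_ir + ac_ir * pulsatile + drift
    red = params.dc_red + ac_red * pulsatile + drift
    if params.noise_sd > 0:
        red = red + rng.normal(0.0, params.noise_sd, size=n)
        ir = ir + rng.normal(0.0, params.noise_sd, size=n)

    red = np.clip(red, 0.0, ADC_FULL_SCALE)
    ir = np.clip(ir, 0.0, ADC_FULL_SCALE)
    return PPGRecording(fs=params.fs, t0=0.0, red=red, ir=ir)


def generate_accel(
    fs: float,
    duration: float,
    bursts: list[tuple[float, float, float]] | tuple = (),
    seed: int = 0,
    noise_sd_mg: float = 0.0,
    baseline: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> AccelTrace:
    """Gravity baseline plus rectangular deviation bursts along the x axis.

    ``bursts`` is a list of ``(start_s, length_s, amplitude_mg)``; bursts
    must lie within the trace and must not overlap.  Deterministic given
    ``seed``.
    """
    if fs <= 0 or duration <= 0:
        raise ValidationError("fs and duration must be positive")
    spans = sorted((s, s + l, a) for s, l, a in bursts)
    for i, (s, e, _a) in enumerate(spans):
        if s < 0 or e > duration:
            raise ValidationError("burst outside the trace span")
        if i > 0 and s < spans[i - 1][1]:
            raise ValidationError("bursts must not overlap")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ax = np.full(n, baseline[0])
    ay = np.full(n, baseline[1])
    az = np.full(n, baseline[2])
    for s, e, amp_mg in spans:
        mask = (t >= s) & (t < e)
        ax[mask] += amp_mg / 1000.0
    if noise_sd_mg > 0:
        ax = ax + rng.normal(0.0, noise_sd_mg / 1000.0, size=n)
        ay = ay + rng.normal(0.0, noise_sd_mg / 1000.0, size=n)
        az = az + rng.normal(0.0, noise_sd_mg / 1000.0, size=n)
    return AccelTrace(fs=fs, ax=ax, ay=ay, az=az)
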