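"""The three vital-sign estimators and the per-window pipeline.

Heart rate: bandpass -> slope sum function -> peak detection -> mean of
instantaneous rates ``60000 / d`` over the collection window.

SpO2: peaks/valleys located on the filtered IR channel, AC (peak minus
adjacent trough) and DC (trough level) measured per beat on the *raw*
channels (filtering removes the DC the ratio needs), per-beat
ratio-of-ratios R, window value = calibration polynomial at the median R.

Respiratory rate: respiration frequency-modulates inter-beat intervals
and amplitude-modulates pulse heights.  Both modulation series are
sampled once per beat at inter-peak midpoints, resampled to a uniform
4 Hz with shape-preserving interpolation, Hamming-windowed and Fourier
transformed; the two unit-normalized power spectra are fused by
element-wise product (suppressing peaks not shared by both mechanisms)
and RR = 60 x the dominant fused frequency in the plausible band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dsp
from .dsp import BeatSeries, SampleSeries
from .errors import (
    DegenerateSignalError,
    InsufficientBeatsError,
    NoEstimateError,
    ValidationError,
    WindowRejectedError,
)
from .oximetry import is_valid_spo2, spo2_from_ratio

#: Plausible respiratory band, Hz (6-40 breaths/min).
RR_BAND = (0.1, 0.66)

#: Instantaneous-HR validity band, bpm; values outside are discarded
#: before averaging.
HR_VALID = (20.0, 240.0)


@dataclass(frozen=True)
class AcDcComponents:
    """Per-window pulsatile and baseline components of both channels."""

    ac_red: float
    dc_red: float
    ac_ir: float
    dc_ir: float

    @property
    def R(self) -> float:
        return compute_ratio(self)


@dataclass
class ModulationSeries:
    """A respiration-induced modulation series sampled once per beat."""

    kind: str  # "FM" (ms) or "AM" (amplitude units)
    t: np.ndarray
    x: np.ndarray
    n_peaks: int


@dataclass
class VitalsRecord:
    """One vitals tuple per collection window; ``None`` marks a vital the
    window could not support."""

    timestamp: float
    hr: float | None
    spo2: float | None
    rr: float | None


def instantaneous_hr(d_ms):
    """Instantaneous heart rate, bpm, from an inter-beat interval in ms:
    ``6e4 / d``.  Accepts scalars or arrays."""
    d = np.asarray(d_ms, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("inter-beat intervals must be positive")
    out = 6.0e4 / d
    return float(out) if np.isscalar(d_ms) else out


def compute_ratio(components: AcDcComponents) -> float:
    """Ratio-of-ratios R = (AC_red/DC_red) / (AC_ir/DC_ir)."""
    if components.dc_red <= 0 or components.dc_ir <= 0 or components.ac_ir <= 0:
        raise DegenerateSignalError("AC/DC components give a zero denominator")
    return (components.ac_red / components.dc_red) / (
        components.ac_ir / components.dc_ir
    )


def compute_spo2(R: float) -> float:
    """Oxygen saturation (percent) from the calibration polynomial.

    Returns the raw polynomial value; use
    :func:`ppgvitals.oximetry.is_valid_spo2` to flag readings outside the
    physiological band (0, 100].
    """
    if R < 0:
        raise ValidationError("ratio R must be nonnegative")
    return spo2_from_ratio(R)


def extract_fm(beats: BeatSeries) -> ModulationSeries:
    """Frequency-modulation series: |t_peak[i-1] - t_peak[i]| in ms,
    timestamped at the midpoint of the two peaks."""
    if len(beats) < 3:
        raise InsufficientBeatsError("FM extraction needs at least 3 peaks")
    x = np.abs(np.diff(beats.t_peak)) * 1000.0
    t = (beats.t_peak[:-1] + beats.t_peak[1:]) / 2.0
    return ModulationSeries(kind="FM", t=t, x=x, n_peaks=len(beats))


def extract_am(beats: BeatSeries, align: str = "midpoint") -> ModulationSeries:
    """Amplitude-modulation series: |y_peak| per beat.

    ``align="midpoint"`` timestamps the series on the same inter-peak
    midpoints as the FM series (the value at each midpoint is the later
    peak's amplitude), so both modulation series share one time base;
    ``align="peak"`` keeps every peak at its own time.
    """
    if len(beats) < 2:
        raise InsufficientBeatsError("AM extraction needs at least 2 peaks")
    y = np.abs(beats.y_peak)
    if align == "midpoint":
        t = (beats.t_peak[:-1] + beats.t_peak[1:]) / 2.0
        x = y[1:]
    elif align == "peak":
        t = beats.t_peak.copy()
        x = y
    else:
        raise ValidationError("align must be 'midpoint' or 'peak'")
    return ModulationSeries(kind="AM", t=t, x=x, n_peaks=len(beats))


def respiratory_rate_from_frequency(f_dominant_hz: float) -> float:
    """Final RR conversion: breaths/min = dominant frequency (Hz) x 60."""
    return f_dominant_hz * 60.0


def _detect_beats_ssf(ir: SampleSeries, zero_phase: bool) -> BeatSeries:
    if np.ptp(ir.values) == 0:  # degenerate flat input has no beats
        return BeatSeries(t_peak=np.empty(0), y_peak=np.empty(0))
    filt = dsp.bandpass_filter(ir, zero_phase=zero_phase)
    ssf = dsp.slope_sum_function(filt)
    return dsp.find_peaks(ssf)


def beats_for_respiration(ir: SampleSeries, zero_phase: bool = True) -> BeatSeries:
    """Beats for the FM/AM analysis: slope-sum timing, filtered-PPG amplitude.

    Beat *timing* comes from the slope-sum detector (robust across heart
    rates); the pulse *amplitude* of each beat is the filtered-PPG
    maximum in a neighbourhood of the slope-sum peak, since the
    amplitude-modulation series needs actual pulse heights rather than
    slope energies.  Troughs between beats are populated as well
    (``t_valley``/``y_valley``) for baseline-corrected amplitude checks.
    """
    filt = dsp.bandpass_filter(ir, zero_phase=zero_phase)
    beats = _detect_beats_ssf(ir, zero_phase)
    if len(beats) < 2:
        return beats
    fs = ir.fs
    half = max(1, int(round(0.4 * np.median(beats.d) / 1000.0 * fs)))
    idx = np.round((beats.t_peak - ir.t0) * fs).astype(int)
    v = filt.values
    y = np.empty(len(idx))
    for k, i in enumerate(idx):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        y[k] = v[lo:hi].max()
    out = BeatSeries(t_peak=beats.t_peak, y_peak=y)
    return dsp.find_valleys(filt, out)


def estimate_hr(ir_window: SampleSeries, zero_phase: bool = True) -> float:
    """Window heart rate: mean of valid instantaneous rates, bpm."""
    beats = _detect_beats_ssf(ir_window, zero_phase)
    if len(beats) < 2:
        raise InsufficientBeatsError("fewer than 2 beats in the window")
    hr_inst = instantaneous_hr(beats.d)
    hr_inst = hr_inst[(hr_inst >= HR_VALID[0]) & (hr_inst <= HR_VALID[1])]
    if hr_inst.size == 0:
        raise InsufficientBeatsError("no instantaneous rates in the valid band")
    return float(hr_inst.mean())


# Minimum relative variability for a modulation series to count as
# carrying respiration.  Dispersion is measured as MAD/median (robust to
# the handful of edge beats distorted by filter transients); the FM floor
# additionally scales with the sample period, since peak times are
# quantized to the sampling grid.
_MIN_AM_DISPERSION = 0.01
_MIN_FM_DISPERSION = 0.005


def _mad_over_median(x: np.ndarray) -> float:
    med = np.median(np.abs(x))
    if med <= 0:
        return 0.0
    return float(np.median(np.abs(x - np.median(x))) / med)


def _fused_spectrum(fm: ModulationSeries, am: ModulationSeries, fs_resample: float):
    fm_u = dsp.resample_pchip(fm.t, fm.x, fs_out=fs_resample)
    am_u = dsp.resample_pchip(am.t, am.x, fs_out=fs_resample)
    nfft = dsp._next_pow2(8 * max(len(fm_u), len(am_u)))
    spec_fm = dsp.power_spectrum(fm_u, nfft=nfft)
    spec_am = dsp.power_spectrum(am_u, nfft=nfft)
    fused = np.ones_like(spec_fm.power)
    for spec in (spec_fm, spec_am):
        peak = spec.power.max()
        fused = fused * (spec.power / peak if peak > 0 else spec.power)
    return dsp.Spectrum(freqs=spec_fm.freqs, power=fused)


def estimate_rr(
    ir_window: SampleSeries,
    band: tuple[float, float] = RR_BAND,
    fs_resample: float = 4.0,
    zero_phase: bool = True,
) -> float:
    """Window respiratory rate via FM/AM spectral fusion, breaths/min.

    Beat timing comes from the slope-sum detector and pulse amplitudes
    from the filtered PPG (see :func:`beats_for_respiration`).  Raises
    :class:`NoEstimateError` when the window carries no detectable
    respiratory modulation or the fused spectrum has no peak in the band.
    """
    beats = beats_for_respiration(ir_window, zero_phase=zero_phase)
    if len(beats) < 4:
        raise InsufficientBeatsError("too few beats for respiratory analysis")
    fm = extract_fm(beats)
    am = extract_am(beats, align="midpoint")

    # No-modulation gate.  FM: interval dispersion must exceed the
    # sampling-grid quantization floor.  AM: the *peak-to-trough* pulse
    # amplitude series must vary — local baseline correction cancels the
    # slow (< 0.1 Hz) ringing that zero-phase filtering leaves in raw
    # peak heights, which true amplitude modulation survives.
    quant_floor = 1.5 * (1000.0 / ir_window.fs) / float(np.median(fm.x))
    fm_flat = _mad_over_median(fm.x) <= max(_MIN_FM_DISPERSION, quant_floor)
    am_flat = True
    if beats.y_valley is not None:
        ptp = beats.y_peak[1:] - beats.y_valley
        am_flat = _mad_over_median(ptp) <= _MIN_AM_DISPERSION
    if fm_flat and am_flat:
        raise NoEstimateError("no detectable respiratory modulation")

    fused = _fused_spectrum(fm, am, fs_resample)
    f_d = dsp.dominant_frequency(fused, band)
    return respiratory_rate_from_frequency(f_d)


def measure_ac_dc(
    red_raw: SampleSeries,
    ir_raw: SampleSeries,
    beats: BeatSeries,
) -> AcDcComponents:
    """Per-beat AC/DC extraction on the raw channels.

    ``beats`` must carry valleys located on a filtered-but-aligned
    channel (zero-phase filtering keeps peak/trough indices aligned with
    the raw samples).  For each beat, AC = raw value at the peak minus
    the raw value at the following trough and DC = the trough level;
    window components are medians across beats.
    """
    if beats.t_valley is None or len(beats) < 2:
        raise InsufficientBeatsError("beats with valleys required")
    fs = ir_raw.fs
    pidx = np.round((beats.t_peak[:-1] - ir_raw.t0) * fs).astype(int)
    vidx = np.round((beats.t_valley - ir_raw.t0) * fs).astype(int)
    ac_red = red_raw.values[pidx] - red_raw.values[vidx]
    dc_red = red_raw.values[vidx]
    ac_ir = ir_raw.values[pidx] - ir_raw.values[vidx]
    dc_ir = ir_raw.values[vidx]
    return AcDcComponents(
        ac_red=float(np.median(ac_red)),
        dc_red=float(np.median(dc_red)),
        ac_ir=float(np.median(ac_ir)),
        dc_ir=float(np.median(dc_ir)),
    )


def estimate_spo2(
    red_window: SampleSeries,
    ir_window: SampleSeries,
    zero_phase: bool = True,
) -> float:
    """Window SpO2: calibration polynomial at the median per-beat R."""
    filt_ir = dsp.bandpass_filter(ir_window, zero_phase=zero_phase)
    peaks = dsp.find_peaks(filt_ir)
    if len(peaks) < 2:
        raise InsufficientBeatsError("fewer than 2 beats in the window")
    beats = dsp.find_valleys(filt_ir, peaks)
    comp = measure_ac_dc(red_window, ir_window, beats)
    return compute_spo2(comp.R)


# Beat-train plausibility gate for whole-window processing: enough valid
# intervals and bounded robust dispersion separate a genuine pulse train
# from threshold crossings of noise.
_MIN_VALID_INTERVALS = 5
_MAX_INTERVAL_DISPERSION = 0.35  # IQR / median of inter-beat intervals


def _beats_plausible(d_ms: np.ndarray) -> bool:
    d_min, d_max = 6.0e4 / HR_VALID[1], 6.0e4 / HR_VALID[0]
    valid = d_ms[(d_ms >= d_min) & (d_ms <= d_max)]
    if valid.size < _MIN_VALID_INTERVALS or valid.size < 0.6 * d_ms.size:
        return False
    q1, med, q3 = np.percentile(valid, [25, 50, 75])
    return (q3 - q1) / med <= _MAX_INTERVAL_DISPERSION


def process_window(
    red: SampleSeries,
    ir: SampleSeries,
    t0: float = 0.0,
) -> VitalsRecord:
    """Turn one gated two-channel window into a vitals record.

    The record is timestamped at the window end.  Each vital is marked
    unavailable (``None``) individually; a window whose beat train fails
    the plausibility gate, or on which all three estimators fail, raises
    :class:`WindowRejectedError`.
    """
    if len(red) != len(ir) or red.fs != ir.fs:
        raise ValidationError("red and ir windows must be aligned")
    timestamp = t0 + len(ir) / ir.fs

    try:
        ssf_beats = _detect_beats_ssf(ir, zero_phase=True)
        if len(ssf_beats) < 2 or not _beats_plausible(ssf_beats.d):
            raise WindowRejectedError("window has no plausible beat train")
    except (InsufficientBeatsError, ValidationError):
        raise WindowRejectedError("window has no plausible beat train")

    hr: float | None
    try:
        hr_inst = instantaneous_hr(ssf_beats.d)
        hr_inst = hr_inst[(hr_inst >= HR_VALID[0]) & (hr_inst <= HR_VALID[1])]
        hr = float(hr_inst.mean()) if hr_inst.size else None
    except (InsufficientBeatsError, ValidationError):
        hr = None

    spo2: float | None
    try:
        value = estimate_spo2(red, ir)
        spo2 = value if is_valid_spo2(value) else None
    except (InsufficientBeatsError, DegenerateSignalError, ValidationError):
        spo2 = None

    rr: float | None
    try:
        rr = estimate_rr(ir)
    except (InsufficientBeatsError, NoEstimateError, ValidationError):
        rr = None

    if hr is None and spo2 is None and rr is None:
        raise WindowRejectedError("all estimators failed on the window")
    return VitalsRecord(timestamp=timestamp, hr=hr, spo2=spo2, rr=rr)
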