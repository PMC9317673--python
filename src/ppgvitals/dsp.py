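"""Signal-processing primitives for PPG analysis.

All operations are pure functions on :class:`SampleSeries`:

* the [0.1, 5] Hz IIR Butterworth bandpass that isolates the pulsatile
  component;
* the slope sum function (SSF), a running sum of positive clipped first
  differences that sharpens systolic upstrokes for beat detection;
* local-maximum peak detection with a refractory period and a relative
  amplitude threshold, and trough detection between beats;
* shape-preserving (PCHIP) resampling of irregular series onto a uniform
  rate;
* mean-removed, Hamming-windowed, zero-padded power spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import maximum_filter1d

from .errors import InsufficientBeatsError, NoEstimateError, ValidationError


@dataclass
class SampleSeries:
    """A uniformly sampled real-valued series."""

    fs: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.values.ndim != 1 or np.any(~np.isfinite(self.values)):
            raise ValidationError("values must be a finite 1-d series")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


@dataclass
class BeatSeries:
    """Detected beats: peak times (s), peak amplitudes, inter-beat
    intervals d (ms), and optionally the troughs between them."""

    t_peak: np.ndarray
    y_peak: np.ndarray
    t_valley: np.ndarray | None = None
    y_valley: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_peak = np.asarray(self.t_peak, dtype=float)
        self.y_peak = np.asarray(self.y_peak, dtype=float)
        if len(self.t_peak) != len(self.y_peak):
            raise ValidationError("t_peak and y_peak must have equal lengths")
        if len(self.t_peak) > 1 and np.any(np.diff(self.t_peak) <= 0):
            raise ValidationError("t_peak must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_peak)

    @property
    def d(self) -> np.ndarray:
        """Inter-beat intervals in milliseconds (length = n_peaks - 1)."""
        return np.diff(self.t_peak) * 1000.0


@dataclass
class Spectrum:
    """One-sided power spectrum; ``f_dominant`` is filled in by callers
    that search a plausible band."""

    freqs: np.ndarray
    power: np.ndarray
    f_dominant: float | None = None


def bandpass_filter(
    series: SampleSeries,
    low: float = 0.1,
    high: float = 5.0,
    order: int = 4,
    zero_phase: bool = False,
) -> SampleSeries:
    """Butterworth bandpass; causal by default (the real-time path),
    forward-backward (zero-phase) optionally for offline analysis."""
    if not 0 < low < high:
        raise ValidationError("need 0 < low < high")
    if high >= series.fs / 2:
        raise ValidationError("high cutoff must be below Nyquist")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=series.fs, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, series.values)
    else:
        out = sps.sosfilt(sos, series.values)
    return SampleSeries(fs=series.fs, values=out, t0=series.t0)


def slope_sum_function(
    series: SampleSeries,
    window_s: float = 0.128,
    exponent: int = 2,
) -> SampleSeries:
    """Slope sum function: trailing-window sum of clipped first differences.

    Differences ``ds_k = x_k - x_{k-1}`` are clipped at zero (only rising
    slopes contribute), raised to ``exponent`` and summed over a trailing
    window.  Output is nonnegative, same length and rate as the input.
    """
    n = len(series)
    w = int(round(window_s * series.fs))
    if w < 1:
        raise ValidationError("window must span at least one sample")
    if w > n:
        raise ValidationError("window longer than the series")
    dx = np.zeros(n)
    dx[1:] = np.clip(np.diff(series.values), 0.0, None) ** exponent
    out = np.convolve(dx, np.ones(w))[:n]
    return SampleSeries(fs=series.fs, values=out, t0=series.t0)


def find_peaks(
    series: SampleSeries,
    refractory_s: float = 0.25,
    rel_threshold: float = 0.5,
    running_window_s: float = 3.0,
) -> BeatSeries:
    """Detect beat peaks as thresholded strict local maxima.

    A candidate is a strict local maximum exceeding ``rel_threshold``
    times the running maximum of the series over a centred
    ``running_window_s`` window.  Candidates closer than ``refractory_s``
    are resolved by amplitude priority (the larger peak wins), which caps
    the detectable rate at ``60 / refractory_s`` bpm.
    """
    if len(series) < 3:
        raise ValidationError("series too short for peak detection")
    v = series.values
    cand = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if cand.size:
        size = max(1, int(round(running_window_s * series.fs)))
        runmax = maximum_filter1d(v, size=size, mode="nearest")
        cand = cand[v[cand] > rel_threshold * runmax[cand]]

    refr = int(round(refractory_s * series.fs))
    accepted: list[int] = []
    # amplitude-priority greedy refractory enforcement (ties -> earlier index)
    for i in sorted(cand, key=lambda i: (-v[i], i)):
        if all(abs(i - j) >= refr for j in accepted):
            accepted.append(i)
    accepted.sort()
    idx = np.asarray(accepted, dtype=int)
    return BeatSeries(t_peak=series.t0 + idx / series.fs, y_peak=v[idx])


def find_valleys(series: SampleSeries, peaks: BeatSeries) -> BeatSeries:
    """Locate the trough (minimum) between each consecutive peak pair.

    Returns a new :class:`BeatSeries` with ``t_valley``/``y_valley``
    populated (one valley per peak pair).
    """
    if len(peaks) < 2:
        raise InsufficientBeatsError("need at least 2 peaks to locate valleys")
    v = series.values
    pidx = np.round((peaks.t_peak - series.t0) * series.fs).astype(int)
    t_val, y_val = [], []
    for a, b in zip(pidx[:-1], pidx[1:]):
        seg = v[a + 1 : b]
        if seg.size == 0:
            raise InsufficientBeatsError("no samples between consecutive peaks")
        k = a + 1 + int(np.argmin(seg))
        t_val.append(series.t0 + k / series.fs)
        y_val.append(v[k])
    return BeatSeries(
        t_peak=peaks.t_peak,
        y_peak=peaks.y_peak,
        t_valley=np.asarray(t_val),
        y_valley=np.asarray(y_val),
    )


def resample_pchip(t: np.ndarray, x: np.ndarray, fs_out: float = 4.0) -> SampleSeries:
    """Shape-preserving piecewise-cubic resampling onto a uniform rate.

    The PCHIP interpolant passes through every input point, preserves
    monotone runs and never overshoots local data extrema.  The output
    spans [t[0], t[-1]] at ``fs_out`` (default 4 Hz).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or len(t) < 2 or len(t) != len(x):
        raise ValidationError("need matching 1-d arrays with at least 2 points")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValidationError("duplicate time points")
    if np.any(dt < 0):
        raise ValidationError("times must be strictly increasing")
    if fs_out <= 0:
        raise ValidationError("fs_out must be positive")
    n_out = int(np.floor((t[-1] - t[0]) * fs_out + 1e-9)) + 1
    t_out = t[0] + np.arange(n_out) / fs_out
    interp = PchipInterpolator(t, x)
    return SampleSeries(fs=fs_out, values=interp(t_out), t0=t[0])


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1)).bit_length()


def power_spectrum(series: SampleSeries, nfft: int | None = None) -> Spectrum:
    """Mean-removed, Hamming-windowed, zero-padded magnitude-squared FFT.

    ``nfft`` defaults to the next power of two at or above 8x the series
    length, giving a frequency-bin spacing fine enough to resolve
    respiratory rates to a fraction of a breath per minute.
    """
    n = len(series)
    if n < 8:
        raise ValidationError("series too short for a spectrum")
    if nfft is None:
        nfft = _next_pow2(8 * n)
    elif nfft < n:
        raise ValidationError("nfft must be at least the series length")
    x = (series.values - series.values.mean()) * np.hamming(n)
    spec = np.fft.rfft(x, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / series.fs)
    return Spectrum(freqs=freqs, power=np.abs(spec) ** 2)


def dominant_frequency(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Frequency of maximum power inside ``band`` (Hz, inclusive)."""
    mask = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    if not mask.any():
        raise NoEstimateError("plausible band contains no spectral bins")
    p = spectrum.power[mask]
    if p.max() <= 0.0:
        raise NoEstimateError("no spectral power in the plausible band")
    return float(spectrum.freqs[mask][int(np.argmax(p))])
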