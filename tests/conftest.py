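import numpy as np
import pytest

from ppgvitals import SampleSeries, SimParams, generate_ppg


def clean_params(**kw) -> SimParams:
    """Noiseless, drift-free generator parameters for deterministic tests."""
    defaults = dict(
        hr_bpm=70.0, rr_brpm=12.0, spo2_pct=96.0, fm_depth=0.1, am_depth=0.1,
        noise_sd=0.0, drift_amp=0.0, duration=30.0, fs=100.0, seed=0,
    )
    defaults.update(kw)
    return SimParams(**defaults)


@pytest.fixture
def clean_window():
    """A clean 30 s two-channel window with known HR/SpO2/RR ground truth."""
    params = clean_params()
    rec = generate_ppg(params)
    red = SampleSeries(fs=rec.fs, values=rec.red)
    ir = SampleSeries(fs=rec.fs, values=rec.ir)
    return params, red, ir


def sine_series(freq_hz, fs=100.0, duration=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return SampleSeries(fs=fs, values=amplitude * np.sin(2 * np.pi * freq_hz * t + phase))
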