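"""Agreement of estimated vs ground-truth heart rate, Bland-Altman style.

Twenty noisy 30 s windows with varying true heart rates: the per-window
estimates are paired with the ground truth by timestamp, then summarised
as bias, limits of agreement and mean percentage error — the same
statistics used to judge a wearable against a reference pulse oximeter.
"""

import numpy as np

import ppgvitals as pv

rng = np.random.default_rng(3)
t, derived, reference = [], [], []
for k in range(20):
    hr = float(rng.uniform(55, 110))
    p = pv.SimParams(hr_bpm=hr, rr_brpm=14.0, spo2_pct=97.0,
                     noise_sd=60.0, duration=30.0, seed=k)
    rec = pv.generate_ppg(p)
    est = pv.estimate_hr(pv.SampleSeries(rec.fs, rec.ir))
    t.append(30.0 * k)
    derived.append(est)
    reference.append(hr)

pairs, unmatched = pv.pair_by_timestamp(t, derived, t, reference, tolerance=1.0)
ba = pv.bland_altman(pairs)
mpe = pv.mean_percentage_error(pairs)
print(f"pairs: {len(pairs)} (unmatched {unmatched})")
print(f"bias {ba.bias:+.3f} bpm, LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] bpm")
print(f"mean percentage error {mpe:.2f} %")
# A near-zero bias with tight limits of agreement means the estimator
# tracks the true rate without systematic or erratic error.
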