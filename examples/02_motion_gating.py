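"""Activity detection and 30 s exclusion gating.

A 2-minute recording with one wrist movement at t = 40 s: the burst
raises an activity event (sustained deviation >= 350 mg for >= 1 s),
the window overlapping it is discarded and accumulation restarts at the
event's end.
"""

import ppgvitals as pv

accel = pv.generate_accel(fs=25.0, duration=120.0, bursts=[(40.0, 2.0, 500.0)])
events = pv.detect_activity(accel, pv.ActivityConfig(mode="absolute"))
print("activity events :", [(float(e.start), float(e.end)) for e in events])

rec = pv.generate_ppg(pv.SimParams(duration=120.0, noise_sd=0.0, drift_amp=0.0))
windows = pv.gate_segments(rec, events)
print("gated windows   :", [(float(w.start), float(w.end)) for w in windows])
# Three 30 s windows survive: [0,30) before the movement, then [42,72)
# and [72,102) after the restart; [30,60) is lost to the event.
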