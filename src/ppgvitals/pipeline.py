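"""End-to-end recording processing: motion gating plus per-window vitals.

Ties the acquisition stage (activity detection, 30 s exclusion gating)
to the per-window estimators, reproducing the device's cadence of one
vitals record per motion-free 30 s of signal.
"""

from __future__ import annotations

import numpy as np

from .acquisition import ActivityConfig, detect_activity, gate_segments
from .dsp import SampleSeries
from .errors import WindowRejectedError
from .synth import AccelTrace, PPGRecording
from .vitals import VitalsRecord, process_window


def process_recording(
    recording: PPGRecording,
    accel: AccelTrace | None = None,
    activity_config: ActivityConfig | None = None,
    window_s: float = 30.0,
) -> list[VitalsRecord]:
    """Produce one vitals record per motion-free window of a recording.

    When an acceleration trace is supplied, activity events are detected
    and windows overlapping them are excluded (accumulation restarts at
    each event's end).  Rejected windows are skipped silently; record
    timestamps are absolute (``recording.t0`` + window end).
    """
    events = detect_activity(accel, activity_config) if accel is not None else []
    windows = gate_segments(recording, events, window_s=window_s)
    records: list[VitalsRecord] = []
    for w in windows:
        a = int(round(w.start * recording.fs))
        b = int(round(w.end * recording.fs))
        red = SampleSeries(fs=recording.fs, values=recording.red[a:b], t0=w.start)
        ir = SampleSeries(fs=recording.fs, values=recording.ir[a:b], t0=w.start)
        try:
            rec = process_window(red, ir, t0=w.start)
        except WindowRejectedError:
            continue
        rec.timestamp += recording.t0
        records.append(rec)
    return records
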