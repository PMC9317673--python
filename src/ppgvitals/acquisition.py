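"""Acquisition control: LED emission adjustment, motion detection, gating.

Mirrors the real-time pre-processing of a wrist-worn PPG device:

* closed-loop adjustment of the LED drive level until the photodetector's
  DC output sits in a usable, non-saturated ADC band (automatic LED
  emission control);
* accelerometer activity detection in two modes — *absolute* (deviation
  from the nominal 1 g gravity vector) and *referenced* (deviation from a
  baseline captured during inactive periods, immune to re-orientation);
* exclusion gating that tiles the motion-free parts of a recording with
  tumbling fixed-length collection windows, restarting after each
  activity event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, ValidationError
from .synth import GRAVITY_NOMINAL, ADC_FULL_SCALE, AccelTrace, PPGRecording, SensorResponseModel


@dataclass(frozen=True)
class AlecConfig:
    """Target ADC band and search parameters for LED emission control."""

    target_low: float
    target_high: float
    initial_level: float = 128.0
    step: float = 1.0
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.target_low < self.target_high < ADC_FULL_SCALE:
            raise ValidationError("need 0 < target_low < target_high < full scale")
        if self.step <= 0 or self.max_iterations < 1:
            raise ValidationError("step and max_iterations must be positive")


@dataclass(frozen=True)
class ActivityConfig:
    """Motion-detection configuration.

    Default threshold/duration follow the device setting of 350 mg
    sustained for at least 1 s; ``reference_refresh_s`` is how often the
    referenced-mode baseline is recaptured during inactive periods.
    """

    mode: str = "referenced"
    threshold_mg: float = 350.0
    min_duration_s: float = 1.0
    reference_refresh_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "referenced"):
            raise ValidationError("mode must be 'absolute' or 'referenced'")
        if self.threshold_mg <= 0 or self.min_duration_s <= 0:
            raise ValidationError("threshold and min_duration must be positive")
        if self.reference_refresh_s <= 0:
            raise ValidationError("reference_refresh_s must be positive")


@dataclass(frozen=True)
class ActivityEvent:
    start: float  # s
    end: float    # s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("event end must exceed start")


@dataclass(frozen=True)
class GatedWindow:
    start: float  # s
    end: float    # s


def alec_adjust(model: SensorResponseModel, config: AlecConfig) -> float:
    """Adjust the LED drive level until the mean ADC output enters the band.

    Bounded linear search: the level moves by ``config.step`` toward the
    target band, one measurement per iteration.  Raises
    :class:`ConvergenceError` when the band cannot be reached within
    ``max_iterations`` (e.g. the sensor saturates below ``target_low``).
    """
    level = float(config.initial_level)
    for _ in range(config.max_iterations):
        out = model.respond(level)
        if config.target_low <= out <= config.target_high:
            return level
        level += config.step if out < config.target_low else -config.step
        level = max(level, 0.0)
    raise ConvergenceError(
        f"no drive level reached [{config.target_low}, {config.target_high}] "
        f"within {config.max_iterations} iterations"
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) index pairs
    with stop exclusive."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def detect_activity(trace: AccelTrace, config: ActivityConfig | None = None) -> list[ActivityEvent]:
    """Detect sustained-acceleration activity events.

    A run of samples whose deviation magnitude (Euclidean norm over the
    three axes) stays at or above the threshold for at least
    ``min_duration_s`` becomes one event.  In absolute mode the deviation
    is taken from the nominal 1 g gravity vector; in referenced mode it is
    taken from a running baseline recaptured every
    ``reference_refresh_s`` during inactive periods, so a constant
    re-orientation produces no events.
    """
    if config is None:
        config = ActivityConfig()
    if trace.n == 0:
        raise ValidationError("empty acceleration trace")
    thr = config.threshold_mg / 1000.0
    samples = trace.samples()

    if config.mode == "absolute":
        dev = np.linalg.norm(samples - GRAVITY_NOMINAL, axis=1)
        above = dev >= thr
    else:
        above = np.zeros(trace.n, dtype=bool)
        ref = samples[0].copy()
        refresh_n = max(1, int(round(config.reference_refresh_s * trace.fs)))
        block_start = 0
        block_clean = True
        for k in range(trace.n):
            dev = float(np.linalg.norm(samples[k] - ref))
            above[k] = dev >= thr
            if above[k]:
                block_clean = False
            if k - block_start + 1 == refresh_n:
                if block_clean:
                    ref = samples[block_start : k + 1].mean(axis=0)
                block_start = k + 1
                block_clean = True

    min_samples = int(np.ceil(config.min_duration_s * trace.fs))
    events = []
    for start, stop in _runs(above):
        if stop - start >= min_samples:
            events.append(ActivityEvent(start=start / trace.fs, end=stop / trace.fs))
    return events


def gate_segments(
    recording: PPGRecording,
    events: list[ActivityEvent],
    window_s: float = 30.0,
) -> list[GatedWindow]:
    """Tile the motion-free portion of a recording with tumbling windows.

    Windows are exactly ``window_s`` long, non-overlapping, and disjoint
    from every activity event; after an event interrupts accumulation the
    next window starts at the event's end (the "sampling restarts" rule).
    Times are relative to the recording start.
    """
    end_time = recording.duration
    evs = sorted(events, key=lambda e: e.start)
    windows: list[GatedWindow] = []
    cursor = 0.0
    eps = 1e-9
    while cursor + window_s <= end_time + eps:
        conflict = None
        for e in evs:
            if e.start < cursor + window_s - eps and e.end > cursor + eps:
                conflict = e
                break
        if conflict is None:
            windows.append(GatedWindow(start=cursor, end=cursor + window_s))
            cursor += window_s
        else:
            cursor = conflict.end
    return windows
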