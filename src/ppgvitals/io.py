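"""Plain-text readers/writers for recordings and acceleration traces.

Recordings travel as CSV with header ``t,red,ir`` plus a JSON sidecar
(same stem, ``.json``) holding the sampling rate, start time and any
ground-truth generator parameters; acceleration as CSV ``t,ax,ay,az``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synth import AccelTrace, PPGRecording, SimParams


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: PPGRecording, path, params: SimParams | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"t": rec.t, "red": rec.red, "ir": rec.ir}).to_csv(path, index=False)
    meta = {"fs": rec.fs, "t0": rec.t0}
    if params is not None:
        meta["ground_truth"] = dataclasses.asdict(params)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> tuple[PPGRecording, dict]:
    """Read a recording CSV; returns (recording, metadata dict).

    Falls back to inferring fs from the time column when no sidecar
    exists.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("t", "red", "ir"):
        if col not in df.columns:
            raise ValidationError(f"recording CSV lacks column {col!r}")
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if "fs" in meta:
        fs = float(meta["fs"])
    else:
        dt = np.diff(df["t"].to_numpy())
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValidationError("cannot infer sampling rate from time column")
        fs = 1.0 / float(np.median(dt))
    rec = PPGRecording(
        fs=fs,
        t0=float(meta.get("t0", 0.0)),
        red=df["red"].to_numpy(),
        ir=df["ir"].to_numpy(),
    )
    return rec, meta


def write_accel(trace: AccelTrace, path) -> None:
    pd.DataFrame(
        {"t": trace.t, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    ).to_csv(Path(path), index=False)


def read_accel(path, fs: float | None = None) -> AccelTrace:
    df = pd.read_csv(Path(path))
    for col in ("t", "ax", "ay", "az"):
        if col not in df.columns:
            raise ValidationError(f"acceleration CSV lacks column {col!r}")
    if fs is None:
        dt = np.diff(df["t"].to_numpy())
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValidationError("cannot infer sampling rate from time column")
        fs = 1.0 / float(np.median(dt))
    return AccelTrace(
        fs=fs,
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
    )
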