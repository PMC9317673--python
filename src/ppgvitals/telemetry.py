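"""Device-to-backend data path emulation.

Covers the transmission unit (URL-encoded payload with keys
``mac, bat, timestamp, hr, spo2, rr``), the Wi-Fi connection state
machine with credential provisioning, offline store-and-forward
buffering in the device's spare flash, and the server-side ingestion:
validation (nulls, types, duplicates, unknown devices) against a
four-table relational store (Users, Devices, Connections,
HealthRecords) backed by sqlite3.

No real networking is involved: transport is an in-process callable and
the HTTPS layer is out of scope.
"""

from __future__ import annotations

import json
import re
import sqlite3
from collections import deque
from dataclasses import dataclass, field
from urllib.parse import parse_qsl, urlencode

from .errors import ValidationError

#: Table-3 payload keys, in wire order.
PAYLOAD_KEYS = ("mac", "bat", "timestamp", "hr", "spo2", "rr")

_MAC_RE = re.compile(r"^([0-9A-Fa-f]{2}:){5}[0-9A-Fa-f]{2}$")

#: Flash budget for offline buffering: 1 MB module flash minus 0.4 MB
#: firmware, at 64 bytes per serialized record.
BUFFER_BYTES = 600_000
RECORD_BYTES = 64
DEFAULT_CAPACITY = BUFFER_BYTES // RECORD_BYTES  # 9830 records


@dataclass(frozen=True)
class Payload:
    """One transmission unit: AP MAC, battery %, epoch timestamp, vitals."""

    mac: str
    bat: int
    timestamp: int
    hr: float
    spo2: float
    rr: float

    def validate(self) -> None:
        if self.mac is None or not _MAC_RE.match(str(self.mac)):
            raise ValidationError(f"malformed MAC address: {self.mac!r}")
        for key in PAYLOAD_KEYS[1:]:
            if getattr(self, key) is None:
                raise ValidationError(f"payload field {key} is null")
        if int(self.timestamp) <= 0:
            raise ValidationError("timestamp must be a positive epoch time")


def encode_payload(p: Payload) -> str:
    """Serialize a payload as an URL-encoded string in Table-3 key order."""
    p.validate()
    return urlencode([(k, getattr(p, k)) for k in PAYLOAD_KEYS])


class IngestReject(Exception):
    """Internal: carries a machine-readable rejection reason."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(detail or reason)
        self.reason = reason


def parse_payload(raw: str) -> Payload:
    """Parse a wire payload; URL-encoded primary, JSON object accepted.

    Raises :class:`IngestReject` with reason ``null_field`` or
    ``bad_type``.
    """
    if raw.lstrip().startswith("{"):
        try:
            fields = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise IngestReject("bad_type", f"malformed JSON: {exc}") from exc
        if not isinstance(fields, dict):
            raise IngestReject("bad_type", "JSON payload must be an object")
    else:
        fields = dict(parse_qsl(raw, keep_blank_values=True))
    for key in PAYLOAD_KEYS:
        if key not in fields or fields[key] is None or fields[key] == "":
            raise IngestReject("null_field", f"missing or null field {key}")
    try:
        p = Payload(
            mac=str(fields["mac"]),
            bat=int(fields["bat"]),
            timestamp=int(fields["timestamp"]),
            hr=float(fields["hr"]),
            spo2=float(fields["spo2"]),
            rr=float(fields["rr"]),
        )
    except (TypeError, ValueError) as exc:
        raise IngestReject("bad_type", str(exc)) from exc
    try:
        p.validate()
    except ValidationError as exc:
        raise IngestReject("bad_type", str(exc)) from exc
    return p


_SCHEMA = """
CREATE TABLE IF NOT EXISTS Devices (
    DeviceId TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS Users (
    UserId   INTEGER PRIMARY KEY AUTOINCREMENT,
    Username TEXT UNIQUE NOT NULL,
    Password TEXT NOT NULL,
    DeviceId TEXT REFERENCES Devices(DeviceId)
);
CREATE TABLE IF NOT EXISTS Connections (
    ConnectionId INTEGER PRIMARY KEY AUTOINCREMENT,
    SSID     TEXT NOT NULL,
    Password TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS HealthRecords (
    UserId    INTEGER NOT NULL REFERENCES Users(UserId),
    DeviceId  TEXT    NOT NULL REFERENCES Devices(DeviceId),
    Timestamp INTEGER NOT NULL,
    Hr   REAL NOT NULL,
    Spo2 REAL NOT NULL,
    Rr   REAL NOT NULL,
    PRIMARY KEY (UserId, DeviceId, Timestamp)
);
"""


class HealthStore:
    """The backend's four-table relational store (sqlite3, in-memory by
    default)."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)

    def register_device(self, mac: str) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO Devices (DeviceId) VALUES (?)", (mac,)
        )
        self.conn.commit()

    def register_user(self, username: str, password: str, mac: str) -> int:
        cur = self.conn.execute(
            "INSERT INTO Users (Username, Password, DeviceId) VALUES (?, ?, ?)",
            (username, password, mac),
        )
        self.conn.commit()
        return int(cur.lastrowid)

    def add_connection(self, ssid: str, password: str) -> int:
        cur = self.conn.execute(
            "INSERT INTO Connections (SSID, Password) VALUES (?, ?)",
            (ssid, password),
        )
        self.conn.commit()
        return int(cur.lastrowid)

    def user_for_device(self, mac: str) -> int | None:
        row = self.conn.execute(
            "SELECT UserId FROM Users WHERE DeviceId = ?", (mac,)
        ).fetchone()
        return None if row is None else int(row[0])

    def record_count(self) -> int:
        return int(self.conn.execute("SELECT COUNT(*) FROM HealthRecords").fetchone()[0])

    def export_csv(self, directory) -> None:
        """Dump each table to ``<directory>/<Table>.csv``."""
        import csv
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for table in ("Users", "Devices", "Connections", "HealthRecords"):
            cur = self.conn.execute(f"SELECT * FROM {table}")
            with open(directory / f"{table}.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow([c[0] for c in cur.description])
                writer.writerows(cur.fetchall())


@dataclass(frozen=True)
class IngestResult:
    accepted: bool
    reason: str | None = None  # null_field | bad_type | duplicate | unknown_device
    payload: Payload | None = None


def validate_and_store(raw: str, store: HealthStore) -> IngestResult:
    """Server-side ingestion of one wire payload.

    Parses and type-checks the payload, rejects null/malformed fields,
    unknown devices (the MAC must exist in ``Devices`` with a registered
    user) and duplicates on the (user, device, timestamp) composite key;
    otherwise inserts one HealthRecords row.
    """
    try:
        p = parse_payload(raw)
    except IngestReject as rej:
        return IngestResult(accepted=False, reason=rej.reason)

    user_id = store.user_for_device(p.mac)
    if user_id is None:
        return IngestResult(accepted=False, reason="unknown_device", payload=p)
    try:
        store.conn.execute(
            "INSERT INTO HealthRecords (UserId, DeviceId, Timestamp, Hr, Spo2, Rr)"
            " VALUES (?, ?, ?, ?, ?, ?)",
            (user_id, p.mac, p.timestamp, p.hr, p.spo2, p.rr),
        )
        store.conn.commit()
    except sqlite3.IntegrityError:
        return IngestResult(accepted=False, reason="duplicate", payload=p)
    return IngestResult(accepted=True, payload=p)


class BufferStore:
    """FIFO store-and-forward buffer with drop-oldest overflow."""

    def __init__(self, capacity: int = DEFAULT_CAPACITY):
        if capacity <= 0:
            raise ValidationError("capacity must be positive")
        self.capacity = capacity
        self.queue: deque[Payload] = deque()
        self.dropped = 0

    def __len__(self) -> int:
        return len(self.queue)

    def push(self, p: Payload) -> None:
        if len(self.queue) >= self.capacity:
            self.queue.popleft()
            self.dropped += 1
        self.queue.append(p)

    def drain(self) -> list[Payload]:
        out = list(self.queue)
        self.queue.clear()
        return out


@dataclass
class TransmissionLog:
    """Outcome of a store-and-forward simulation: payloads actually
    transmitted (in order), payloads dropped on overflow, and payloads
    still queued when the stream ended."""

    delivered: list[Payload] = field(default_factory=list)
    dropped: int = 0
    pending: list[Payload] = field(default_factory=list)


def buffer_and_flush(
    records: list[Payload],
    connectivity: list[bool],
    capacity: int = DEFAULT_CAPACITY,
) -> TransmissionLog:
    """Simulate offline buffering across an outage pattern.

    At each step one record is produced.  While disconnected it queues
    (FIFO, oldest dropped beyond ``capacity``); at a connected step the
    backlog transmits in order before the new record.
    """
    if len(records) != len(connectivity):
        raise ValidationError("records and connectivity must have equal length")
    buf = BufferStore(capacity=capacity)
    log = TransmissionLog()
    for p, online in zip(records, connectivity):
        if online:
            log.delivered.extend(buf.drain())
            log.delivered.append(p)
        else:
            buf.push(p)
    log.dropped = buf.dropped
    log.pending = buf.drain()
    return log


# Connection-manager states
TRY_SAVED = "try_saved"
CONNECTED = "connected"
AP_MODE = "ap_mode"
REBOOT = "reboot"


@dataclass
class ConnectionOutcome:
    states: list[str]
    connected: bool
    credentials: list[tuple[str, str]]
    ap_mac: str | None


def connection_manager(
    saved: tuple[str, str] | None,
    attempt_results,
    new_credentials: tuple[str, str] | None = None,
    access_points: list[tuple[str, float]] | tuple = (),
) -> ConnectionOutcome:
    """Deterministic Wi-Fi connection state machine.

    Tries the previously saved credentials first; on failure enters AP
    (provisioning) mode, stores newly provided credentials, reboots and
    retries.  ``attempt_results`` maps SSID -> bool (or is a callable
    ``(ssid, password) -> bool``).  When connected, the MAC of the
    strongest access point in ``access_points`` (``(mac, rssi_dbm)``
    pairs) is the one attached to subsequent payloads.
    """
    if callable(attempt_results):
        attempt = attempt_results
    else:
        results = dict(attempt_results)
        attempt = lambda ssid, pw: bool(results.get(ssid, False))

    creds: list[tuple[str, str]] = [saved] if saved else []
    states: list[str] = []
    connected = False

    if saved is not None:
        states.append(TRY_SAVED)
        connected = attempt(*saved)
        if connected:
            states.append(CONNECTED)

    if not connected:
        states.append(AP_MODE)
        if new_credentials is not None:
            creds.append(new_credentials)
            states.extend([REBOOT, TRY_SAVED])
            connected = attempt(*new_credentials)
            states.append(CONNECTED if connected else AP_MODE)

    ap_mac = None
    if connected and access_points:
        ap_mac = max(access_points, key=lambda ap: ap[1])[0]
    return ConnectionOutcome(
        states=states, connected=connected, credentials=creds, ap_mac=ap_mac
    )
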