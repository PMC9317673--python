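"""Telemetry path: payload encoding, offline buffering, ingestion.

Six vitals payloads are produced while Wi-Fi drops for records 1-3; the
device buffers them and flushes in order on reconnection.  The backend
validates each wire payload against the relational store.
"""

import ppgvitals as pv

payloads = [
    pv.Payload("AA:BB:CC:DD:EE:FF", 90 - i, 1_650_000_000 + 30 * i, 71.5, 96.8, 14.2)
    for i in range(6)
]
print("wire format:", pv.encode_payload(payloads[0]))

online = [True, False, False, False, True, True]
log = pv.buffer_and_flush(payloads, online, capacity=100)
print(f"delivered {len(log.delivered)}/6 in order, dropped {log.dropped}")

store = pv.HealthStore()
store.register_device("AA:BB:CC:DD:EE:FF")
store.register_user("alice", "secret", "AA:BB:CC:DD:EE:FF")
for p in log.delivered:
    res = pv.validate_and_store(pv.encode_payload(p), store)
    assert res.accepted
dup = pv.validate_and_store(pv.encode_payload(payloads[0]), store)
print(f"stored rows: {store.record_count()}; duplicate resubmission -> {dup.reason}")
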