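# ppgvitals

A desk-scale, fully testable re-creation of the vital-signs computation
chain of a wrist-worn photoplethysmography (PPG) device: two-wavelength
signal acquisition control, accelerometer motion gating, bandpass
filtering, and real-time-style extraction of heart rate (HR), blood
oxygen saturation (SpO2) and respiratory rate (RR) — together with a
synthetic-signal generator that provides known ground truth, a telemetry
emulation of the device-to-backend path, and the agreement statistics
used to judge such a device against clinical references.

It is written for biomedical-signal-processing practitioners who want to
study, stress or extend each stage of a wearable pipeline without any
hardware: every stage is a pure function on in-memory series, and every
downstream estimator can be validated against the generator's ground
truth.

## The processing chain

**Acquisition control.** LED drive is adjusted in closed loop until the
photodetector's DC output sits in a usable, non-saturated ADC band
(automatic LED emission control). A 3-axis accelerometer gates the PPG:
a sustained deviation of at least 350 mg for at least 1 s raises an
*activity event*, the overlapping signal is discarded, and collection
restarts after the event — yielding tumbling motion-free 30 s windows.
Activity detection runs in an *absolute* mode (deviation from the
nominal 1 g gravity vector) or a *referenced* mode (deviation from a
baseline recaptured during inactive periods, immune to re-orientation).

**Heart rate.** The IR channel is bandpassed to [0.1, 5] Hz (IIR
Butterworth), then the slope sum function

&nbsp;&nbsp;&nbsp;&nbsp;SSF_i = Σ_k Δx_k²,&nbsp;&nbsp;Δx_k = max(Δs_k, 0)

over a trailing window sharpens each systolic upstroke. Beats are local
maxima of the SSF; each inter-beat interval *d* (ms) gives an
instantaneous rate HR_inst = 6·10⁴ / d, and the window's HR is the mean
of the valid instantaneous rates.

**SpO2.** Peaks and valleys located on the filtered IR channel index the
raw channels per beat: AC = peak − adjacent trough, DC = trough level.
The ratio-of-ratios

&nbsp;&nbsp;&nbsp;&nbsp;R = (AC_red / DC_red) / (AC_ir / DC_ir)

feeds the sensor vendor's empirical calibration
SpO2 = −45.006 R² + 30.354 R + 94.84 (%), evaluated at the per-window
median R.

**Respiratory rate.** Respiration frequency-modulates inter-beat
intervals (FM) and amplitude-modulates pulse heights (AM). Both series,
sampled once per beat at inter-peak midpoints, are resampled to a
uniform 4 Hz with shape-preserving (PCHIP) interpolation,
Hamming-windowed and Fourier transformed; the two unit-normalized power
spectra are fused by element-wise product, which keeps only peaks the
two mechanisms share. RR = 60 · F_d, with F_d the dominant fused
frequency in the plausible band (0.1–0.66 Hz).

**Telemetry.** Each 30 s record is serialized as an URL-encoded payload
(`mac, bat, timestamp, hr, spo2, rr`), buffered FIFO in spare flash
during outages (drop-oldest beyond ~9830 records) and flushed in order
on reconnection; the backend validates nulls, types, duplicates and
unknown devices against a four-table relational store (Users, Devices,
Connections, HealthRecords).

**Evaluation.** Derived and reference streams are paired by timestamp
and summarised with Bland–Altman bias and ±1.96 SD limits of agreement,
plus the mean percentage error mean(100·|derived − ref| / ref).

## Worked example

`examples/03_vitals_pipeline.py` runs five clean synthetic minutes
(HR 70 bpm, SpO2 96 %, RR 12 brpm) through the full chain:

```
timestamp   HR bpm   SpO2 %  RR brpm
       30    70.47    96.00    11.95
       60    70.65    96.00    11.95
       90    70.59    96.00    11.95
      ...
      300    70.58    96.00    11.95

10 records at 30 s cadence; compare with ground truth (70 bpm, 96 %, 12 brpm).
```

One record per motion-free 30 s window; HR lands within half a beat per
minute of truth (the small positive offset is the expected convexity
bias of averaging instantaneous rates under frequency modulation), SpO2
is recovered to hundredths of a point, and RR to within the spectral
bin width. The other examples cover the generator
(`01_simulate_ppg.py`), motion gating (`02_motion_gating.py`), the
telemetry round trip (`04_telemetry_roundtrip.py`) and agreement
analysis (`05_agreement_analysis.py`); each prints what it computes and
states what the numbers mean.

A thin CLI mirrors the stages:

```
ppgvitals simulate --hr 70 --rr 12 --spo2 96 --duration 120 --out rec.csv
ppgvitals process --ppg rec.csv --out vitals.csv
ppgvitals evaluate --derived vitals.csv --reference ref.csv --metric hr
```

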