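# Methods

This note records the models, parameter choices and numerical decisions
behind `ppgvitals`, and what the synthetic experiments do and do not
demonstrate about real wrist-worn data.

## Synthetic signal model

The generator emulates the *structure* a two-wavelength wrist PPG
pipeline relies on, not tissue optics. Beat onsets are laid down
iteratively: the instantaneous period is d₀·(1 + m_FM·sin 2πf_R t) with
d₀ = 60/HR s and f_R the respiratory frequency, so inter-beat intervals
carry sinusoidal frequency modulation of fractional depth `fm_depth`.
Each beat is an asymmetric gamma-like template
T(φ) = (φ/φ₀)^k · e^{k(1−φ/φ₀)} on normalized beat phase φ ∈ [0, 1),
with φ₀ = 0.3 and k = 3: a fast systolic rise to a single maximum and a
slow diastolic decay. Per-beat amplitudes are scaled by
1 + m_AM·sin 2πf_R t (depth `am_depth`).

Both channels share one normalized pulsatile waveform:
IR = DC_ir·(1 + p·T), RED = DC_red·(1 + R·p·T), with p the IR perfusion
(AC/DC fraction, default 0.02 — typical of low wrist perfusion) and R
the ratio-of-ratios obtained by inverting the SpO2 calibration
quadratic on its decreasing branch. The measured ratio-of-ratios of the
clean waveform therefore equals the inverted target exactly, and common
rescaling of the two DC levels cancels. The calibration peaks at
R\* = 30.354/(2·45.006) ≈ 0.3372 with SpO2 ≈ 99.96 %, which caps the
requestable saturation.

Nuisance components: additive white Gaussian noise per channel (SD in
ADC counts, default 25), common-mode sinusoidal baseline wander
(default 500 counts at 0.05 Hz), and clipping to an 18-bit ADC range.
Defaults — 100 Hz PPG sampling, 25 Hz accelerometer, DC levels around
1.2–1.5·10⁵ counts — are engineering choices representative of a
low-power optical front end; none is a claim about any particular
hardware. Acceleration traces are a gravity baseline plus rectangular
deviation bursts along one axis, so deviation magnitude equals the
burst amplitude by construction.

What the generator does **not** emulate: pulse-morphology variability
(dicrotic notch, stiffness changes), respiratory baseline (intensity)
modulation, motion artifacts *inside* the optical channel, skin-tone or
contact-pressure effects, and sensor nonlinearity. Passing recovery
tests therefore shows the chain is *self-consistent and correctly
implemented*, not that it meets any accuracy figure on human wrists.

## Acquisition control

LED emission control is a bounded linear search: the drive level moves
by `step` toward the target ADC band, one noise-free mean measurement
per iteration, up to `max_iterations` (50); an unreachable band (e.g. a
sensor saturating below it) raises a convergence error. Activity
magnitude is the Euclidean norm of the 3-axis deviation; absolute mode
references the nominal 1 g vector, referenced mode a running baseline
recaptured every 1 s from fully inactive blocks (initialized from the
first sample, which makes a pre-existing re-orientation invisible, as
intended). An event requires the deviation to stay at or above 350 mg
for at least 1 s — the boundary amplitude itself triggers. Gating tiles
event-free time with tumbling 30 s windows and restarts accumulation at
each event's end; windows are exactly 30 s, so trailing partial signal
is discarded.

## Estimators

* **Filtering.** 4th-order Butterworth bandpass [0.1, 5] Hz as
  second-order sections; causal by default (the real-time path), with a
  zero-phase forward–backward option used by the window pipeline so
  that peak/trough indices stay aligned with the raw samples the SpO2
  ratio needs.
* **Slope sum function.** Positive-clipped first differences raised to
  an exponent (default 2; exponent 1 gives the classical variant — peak
  *locations*, which all HR arithmetic uses, are unchanged) summed over
  a trailing 128 ms window.
* **Peak detection.** Strict local maxima above 0.5× a centred 3 s
  running maximum, with a 250 ms refractory period resolved by
  amplitude priority (larger peak wins); this caps detectable rates at
  240 bpm. Instantaneous rates outside [20, 240] bpm are discarded
  before averaging.
* **Beats for respiration.** Beat timing comes from the slope-sum
  detector; pulse amplitudes are read off the filtered PPG near each
  slope-sum peak. Near the upper end of the passband the filter's 5 Hz
  edge modulates filtered pulse *amplitudes* with FM phase, so
  thresholded maxima of the filtered waveform alone drop beats at high
  heart rates, while slope-sum timing stays intact.
* **SpO2.** Per beat, AC = raw value at the peak minus the raw value at
  the following trough, DC = the trough level (raw channels keep the DC
  that filtering removes); window components are medians across beats —
  robust to single-beat outliers.
* **RR.** FM samples |t_i−1 − t_i| (ms) and AM samples |y_i| share the
  inter-peak-midpoint time base (the AM value at each midpoint is the
  later peak's amplitude; per-peak alignment is available as an
  option). Both are PCHIP-resampled to 4 Hz, mean-removed,
  Hamming-windowed and zero-padded to the next power of two ≥ 8× the
  series length (≈ 0.004 Hz bins for a 30 s window), and the
  unit-max-normalized power spectra are multiplied element-wise — a
  fusion that suppresses peaks not shared by both mechanisms. The
  plausible band is 0.1–0.66 Hz (6–40 brpm).

**No-modulation gate.** A window yields no RR when both modulation
series are flat: FM counts as flat when its MAD/median falls at or
below max(0.005, 1.5 sample periods / median interval) — beat times are
quantized to the sampling grid, so the floor scales with 1/f_s; AM
counts as flat when the *peak-to-trough* amplitude series has
MAD/median ≤ 0.01. Raw peak heights cannot be used for this check: the
0.1 Hz high-pass edge of zero-phase filtering leaves a slow (< 0.1 Hz)
ring across a 30 s window that local baseline correction cancels but
absolute peak values retain. On synthetic data the two regimes separate
by better than a factor of two on either side of these thresholds.

**Window plausibility.** A window is rejected outright when its beat
train is implausible: fewer than 5 valid intervals, fewer than 60 % of
intervals in the valid band, or an interval IQR/median above 0.35 —
thresholds that pass physiological FM depths (IQR/median ≈ 0.14 at 10 %
depth) while rejecting the erratic trains that threshold crossings of
noise produce. Each vital is otherwise independently markable
unavailable; the record carries the window-end timestamp.

## Known limitations

* **Respiration above the beat-sampling Nyquist rate.** The FM/AM
  series are sampled once per beat, so a respiratory frequency above
  half the beat rate aliases: at HR 50 bpm (0.833 Hz beats) a 30 brpm
  (0.5 Hz) breath folds to ≈ 0.33 Hz and is reported as ≈ 20 brpm.
  This is a physical limit of per-beat modulation analysis, not an
  implementation artifact; such HR/RR combinations are physiologically
  rare.
* Averaging instantaneous rates under FM carries a small convexity
  bias, ≈ HR·m_FM²/2 (≈ 0.5 % at 10 % depth) — visible in the worked
  example and well inside the error budget.
* The telemetry layer is an in-process emulation: URL-encoded (or
  JSON) payloads against an sqlite3 store; no real transport, TLS or
  authentication. Buffer capacity assumes 64-byte serialized records in
  a 0.6 MB flash budget (9830 records), with drop-oldest overflow
  favouring recency.
* Bland–Altman limits of agreement use the sample (n−1) SD; the mean
  percentage error uses absolute differences, so signed cancellation is
  not reported.

## Problem sizes

The default test and reproduction runs use 30 s windows at 100 Hz
(3000 samples/channel), a 100-point recovery grid
(HR {50,70,90,110,150} × RR {8,12,18,24,30} × SpO2 {85,90,95,99}),
5-minute recordings for cadence checks, and 100–1000 random instances
per property/oracle check — sizes chosen so the whole suite completes
in seconds on one core while still exercising every code path.
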