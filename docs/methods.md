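# Methods

This note documents the models, parameter choices and numerical decisions
behind `ppgbreathe`, and what the synthetic experiments do and do not show.

## Signal model of the synthetic generator

A breathing protocol defines a piecewise nominal rate `br(t)` (bpm); the
breathing phase is `φ(t) = 2π ∫ br/60 dt`. Inhalation is the half-cycle
with `sin φ > 0`. One subject's PPG is synthesized as

* **FM/RSA** — beats are placed iteratively with instantaneous heart rate
  `hr(t) = hr₀ · (1 + d_rsa · sin φ(t))`, so beat intervals are shorter
  during inhalation (the physiological sign convention);
* **pulse shape** — each beat contributes a two-Gaussian template (systolic
  lobe at 30% of the beat period, width 12%; diastolic lobe at 65%, width
  18%, relative amplitude 0.35), giving a plausible asymmetric pulse whose
  fundamental lies in the 0.5–2.75-Hz cardiac band;
* **AM** — the pulse amplitude is `1 + d_am · sin φ(t_beat)`;
* **BW** — the signal rides on `A_bw · sin φ(t)`;
* **noise** — additive white Gaussian noise on the PPG; the accelerometer is
  gravity (1 g on z) plus white noise;
* **motion bursts** — a burst adds a random-frequency (3–6 Hz) oscillation
  of the given intensity to all three accelerometer axes and band-limited
  (0.5–8 Hz) noise scaled by 3× intensity to the PPG, reproducing the
  empirical phenomenology that motion corrupts both streams simultaneously.

Random draw order per recording is fixed and documented in
`generate_recording` (beat offset → PPG noise → accel noise → per-burst
draws), so a recording is a pure function of `(protocol, params)` and
adding bursts leaves the pre-burst samples bit-identical — which is what
lets the gating experiment compare corrupted and clean runs window by
window.

Default subject parameters (drawn per subject in cohorts): heart rate
60–90 beats/min, RSA depth 0.03–0.08 (a few percent of the beat interval,
typical of adults at rest), AM depth 0.05–0.20, baseline-wander amplitude
0.2–0.5 pulse units, PPG noise SD 0.05–0.15 pulse units ("mild noise"),
accelerometer noise 0.02 g. These are the study conditions used by the test
suite and the acceptance script.

The guided-breath protocol (3-s × 10, 5-s × 8, 8-s × 6 breaths) is labeled
with the nominal cycle rate `60/(breath + pause)` bpm. The published session
arithmetic is not exactly decomposable (one 1-s pause per cycle gives
142 s, not the stated 140 s), so pause placement is a generator parameter
(`pause_s`) rather than a hard-coded guess.

### What the generator does *not* emulate

Pulse-morphology changes with posture or vascular tone, sensor decoupling
(signal dropout rather than additive noise), breathing-rate drift inside a
protocol segment, baseline-wander from sources other than respiration, and
subject non-compliance with the guided protocol. Passing the synthetic
acceptance experiments therefore shows that the pipeline recovers breathing
rate when the three modulations are present at realistic depths and that the
gating logic behaves as designed — not that the headline accuracy
transfers to any particular real-world recording.

## Pipeline decisions

* **Filter family** — the filter type is a free choice; we use third-order
  Butterworth band-passes (maximally flat passband) applied zero-phase with
  `sosfiltfilt` inside each window, since phase distortion would bias peak
  timing and processing is offline. Per-window filtering is the default; the
  segmentation API accepts pre-filtered continuous input by construction
  (filters are length-preserving and linear).
* **Moving-average widths** — 5 samples (0.2 s) on the cardiac path, 25
  samples (1 s) on the respiration path; winsorization at the 1st/99th
  percentiles. All exposed in `RunConfig`.
* **Window labels** — duration-weighted mean of the true rate over the
  window; windows straddling a protocol boundary keep the weighted label and
  are flagged (`straddles_boundary`), matching a sliding-window evaluation.
* **Motion threshold** — "upper extreme value" of the calibration
  distribution is implemented as the Tukey upper fence Q3 + 1.5·IQR
  (default) because a raw maximum is unstable under a single glitch;
  `max` and percentile modes are available. The threshold carries the units
  of the accelerometer stream, so calibration and deployment must share
  units.
* **Rule-2 edge exemption** — a bad run is "at the beginning/end" iff it
  includes the first or last second; longer edge-anchored runs are also
  exempt. Note the exemption makes the rule non-monotone in the bad mask
  (extending an interior run until it touches an edge can rescue a window);
  this is inherent to the exemption, not a bug.
* **Peak detector** — `find_peaks` with (i) minimum separation
  `max(60/220 s, 0.6/f_card)` where `f_card` is the coarse Welch-dominant
  cardiac frequency of the window, and (ii) an amplitude floor equal to the
  rolling 60th percentile over 2 s plus a prominence floor of 0.25·SD.
  Documented operating point: recall and precision ≥ 0.95 against generator
  beat times at noise SD 0.1 (asserted in the test suite).
* **P-P series** — intervals are indexed at their closing peak (an interval
  is known only once its closing peak occurs). Intervals whose bounding
  peaks lie in different clean segments are invalid; the Hampel filter
  (half-window 3, 3 scaled MADs — the filter's conventional defaults) runs
  within valid runs only; quadratic oversampling to 25 Hz uses the longest
  valid run and never bridges an excised gap, because a quadratic spline
  across a multi-second hole fabricates oscillations in exactly the band the
  features read.
* **Welch spectra** — Hann window, 10-s segments, 50% overlap, zero-padded
  to a ≤ 0.025-Hz grid. Dominant-peak amplitudes are √power normalized by
  the largest peak (scale invariance across subjects/sensors); the 10-bin
  0–2-Hz distribution sums √power per bin and normalizes to unit sum so the
  bins form a distribution. Both the P-P and the PPG spectral groups use
  the Welch estimate.
* **"Average increasing time"** — defined here as the mean duration, in
  seconds of signal time, of maximal strictly-increasing runs of consecutive
  P-P intervals (runs of ≥ 2 intervals; 0 if none). The definition is
  isolated in `prv_features`.
* **Peak–valley features** — computed on the oversampled P-P series after a
  0.4-s moving average, with a prominence floor of 5% of the window's series
  range to suppress grid jitter.
* **Regressor** — XGBoost with squared-error objective, 300 trees, learning
  rate 0.05, depth 4, subsample 0.8, single-threaded `hist`, fixed seed:
  conservative settings for tables of ~10³ correlated rows. All three route
  models are trained on all windows (with their feature subsets); missing
  groups are NaN and handled natively by the trees. Predictions are clipped
  to 4–40 bpm to stop pathological tree extrapolation.
* **Baselines** — both spectral baselines search 0.1–0.5 Hz, the band of
  spontaneous breathing; a constant P-P series has no in-band peak and
  yields no estimate.
* **Evaluation** — LOSO; abstained windows are excluded from MAE/PCC and
  counted separately; pooled metrics are computed over the concatenation of
  all test folds (per-subject values are also reported, so either view is
  recoverable). Overlapping windows from the 1-s slide are statistically
  correlated; this is documented, not corrected.

## Problem sizes

The acceptance experiments use a 10-subject cohort breathing at
9/12/15/18 bpm (60 s per rate) with a 2-s window stride (~1.1k windows),
and a 4-s stride inside the window-size sweep; these sizes give stable
pooled metrics (hundreds of windows per fold) while keeping a full run in
the low minutes on one core. The stride is an analysis choice, not a
generator condition; the 1-s slide remains the library default.

## Known limitations

* The quality scheme is accelerometer-only; PPG-morphology quality indices
  are out of scope, so motion-free signal corruption (e.g. contact loss)
  is not detected.
* Quadratic oversampling requires ≥ 3 valid intervals; very sparse windows
  are flagged pulse-undetectable and lose the P-P feature groups even when
  Rule 1 passes.
* The synthetic cohort's rates are piecewise constant; the model has never
  seen continuous rate drift.
* LOSO with ~10 synthetic subjects measures generalization across generator
  parameter draws, a much easier population than real inter-subject
  physiology.
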