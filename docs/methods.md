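# Methods

This note documents the models, parameter choices and numerical decisions
behind `cbpval`, and what the synthetic-data generator does and does not
emulate.

## Study design being reproduced

The pipeline implements the invasive validation methodology for cuff-based
central blood pressure (cBP) estimators: simultaneous recording of an
aortic pressure waveform (fluid-filled catheter) and an oscillometric
cuff deflation; per-beat analysis of the invasive signal; exclusion of
hemodynamically unstable recordings (beat-to-beat SD of SBP/MAP/DBP above
10/6/6 mmHg, strict inequalities) and of severe arrhythmia (more than 30%
of beats cleared, strict); catheter QC by fast-flush test; and
Bland–Altman agreement with protocol grading (ARTERY 2017, AAMI 2013,
AAMI/ESH/ISO 2018, BHS). The difference sign is invasive − estimated
throughout, so a positive mean difference means the device underestimates.

The reference dataset behind this design is not publicly available, so the
package ships a first-class generator whose defaults encode the published
study conditions: 145 analysable of 191 recorded patients; invasive
central SBP/MAP/DBP ≈ 145.1 (24.0) / 101.5 (14.8) / 72.1 (12.2) mmHg;
heart rate 69 (12.2) /min; three sites recording at 240, 500 and 2000 Hz
for 90, 20 and 90 s; cuff deflation at 4 mmHg/s; catheter natural
frequency 21.9 Hz (range 15–29) and damping 0.21 (0.14–0.29); and a
device-error model N(0.71, 5.95²) / N(0.19, 3.78²) / N(2.96, 5.21²) mmHg
for SBP/MAP/DBP.

## Synthetic beat morphology

Each beat is analytic on normalised time `u ∈ [0, 1)`:

* raised-cosine systolic upstroke on `[0, a]` (default upstroke fraction
  `a = 0.20` of the cycle), rising from the foot pressure to SBP;
* diastolic relaxation `0.5·(1 + cos(π·u_d^p))` on the remaining span,
  falling from SBP to the **next** beat's foot pressure with zero slope at
  the landing, so the sampled minimum attains the foot value at any
  sampling rate;
* an optional raised-cosine dicrotic notch (default depth 10% of pulse
  height, capped so the pulse stays monotone-positive).

The warp exponent `p` is the single free shape parameter. Its relation to
the beat's time-average is precomputed on a monotone table and the exact
value is solved per beat (Brent's method) so the rendered beat's mean
equals the requested per-beat MAP; the attainable MAP fraction
`(MAP − DBP)/(SBP − DBP)` is `(a/2, 1 − a/2)` and anything outside raises
a parameter error.

Consecutive beats share foot pressures, which makes the rendered signal
continuous at every foot. Ground-truth per-beat DBP is therefore
`min(foot_i, foot_{i+1})` — exactly the lowest point of that beat.

Beat-to-beat variability is AR(1) with lag-1 correlation 0.6 (emulating
respiratory/Mayer-wave modulation) and marginal SDs 4.08 / 2.31 mmHg for
SBP / foot pressure with a per-beat MAP-fraction jitter of 0.025 (clipped
to the physiologic band 0.20–0.65); these reproduce the per-recording SDs
reported for stable patients (≈4.1 / 2.3 / 2.8 mmHg). Heart-period jitter
is 2%. Measurement noise is additive white Gaussian, default SD 0.5 mmHg
(a placeholder — real catheter noise is unspecified).

Pathologies:

* **Extrasystoles** — interpolated ectopics: a beat with its pulse
  pressure reduced (default 25%; severe-arrhythmia patients use
  U(30%, 50%)) and a coupling interval of 60% of the cycle, with no
  compensatory pause by default (`ectopic_pause_frac` enables one). Clean
  patients carry a 2% Bernoulli ectopic rate ("several extrasystoles" per
  90-s recording); severe-arrhythmia patients an exact 40% fraction placed
  among beats certain to fit the recording, which yields ≈40% of beats
  cleared — safely above the 30% exclusion threshold while keeping the
  flagged fraction below the 50% breakdown point of the MAD-based rule.
* **Hemodynamic instability** — a slow coherent sinusoidal drift of the
  whole pressure level (default amplitude 21 mmHg, period 10 s), which
  moves SBP, MAP and DBP together without touching pulse pressure; the
  recording-level SD becomes ≈ amplitude/√2 ≈ 15 mmHg, deterministically
  above the 10-mmHg SBP limit.
* **Acquisition failure** (zeroing error stand-in) — a flat trace, which
  the detector rejects ("no beats").

## Oscillometric recording model

The cuff signal is a linear deflation (default 4 mmHg/s from SBP+40 mmHg)
plus one pulse per cardiac cycle whose amplitude follows a Gaussian
envelope in cuff-minus-MAP pressure (width 25 mmHg, peak 3 mmHg) — the
standard idealisation; the envelope maximum sits exactly where the cuff
passes MAP. The device sampling rate defaults to 500 Hz. That choice is
deliberate: with 0.5 mmHg per-sample noise, per-pulse amplitude estimation
is matched-filter bounded at ≈0.2 mmHg for a 100-Hz channel, which makes
envelope-MAP recovery within 2 mmHg impossible at any algorithm; at
500 Hz the bound drops to ≈0.09 mmHg and the pipeline recovers MAP with a
maximum error of ≈0.9 mmHg over 200 randomised recordings (heart rate
50–110 /min, MAP 70–140 mmHg).

What the generator does **not** emulate: wave reflection and pulse-shape
change along the arm, cuff-soft-tissue coupling nonlinearity, motion
artifacts with realistic spectra, inflation-phase oscillometry, and any
relation between the true brachial-to-central transform and the surrogate
estimator. Passing round-trip tests therefore demonstrates the
*pipeline's* correctness under controlled conditions, not device accuracy
on real patients.

## Invasive analysis

Beat feet are the minima of a 15-Hz zero-phase-filtered copy of the signal
between successive upstroke events (derivative ≥40% of the recording's
peak slope, floored at 25 mmHg/s, 250 ms refractory period). Values are
taken from the raw samples: SBP = beat maximum, DBP = beat minimum, MAP =
trapezoidal integral over the half-open beat divided by its duration (the
only normalisation that preserves DBP ≤ MAP ≤ SBP). Under 0.5 mmHg noise
the raw extremes carry a small extreme-value bias (SBP reads ≈+0.5 mmHg
high, DBP ≈1–2 mmHg low); this is inherent to the peak/lowest-point
definition and is visible as an offset in the cohort-level DBP mean
difference.

Outlier clearing automates the visual "differed greatly from the mean"
rule as median ± k·robust-SD (k = 3, robust SD = 1.4826·MAD) on per-beat
SBP, DBP **and beat duration**. The duration metric is what makes the rule
sensitive to extrasystoles: an ectopic with a strongly attenuated pulse
falls below the 40%-slope detection threshold and can never be flagged by
amplitude, whereas its short cycle and the compensatory pause are
unambiguous. Robust SDs are floored (1 mmHg for pressures — measurement
resolution; 4% of the median cycle for durations — foot-localisation
jitter on flat diastolic tails) so near-identical recordings flag nothing.
Statistics are computed over all beats, making the rule idempotent.

Verdict order: arrhythmia (cleared fraction > 30%) is checked before
stability; stability sub-reasons are attributed in the order SBP, MAP,
DBP (first limit exceeded wins), matching how disjoint exclusion counts
are reported.

## Catheter QC

The flush release is the largest negative step; the settled baseline is
the mean of the final 20% of the trace. Extrema after release are refined
to sub-sample precision by a three-point parabola (one sample at 1 kHz is
≈1 Hz of quantisation on a 20-Hz ring-down). Oscillations are the
same-sign extrema; the 2nd and 3rd are one full period apart, giving
`fn = 1/(t3 − t2)` and, from their amplitude ratio, the logarithmic
decrement `δ = ln(A2/A3)` and `ζ = δ/√(4π² + δ²)`.

Strictly, `1/(t3 − t2)` measures the *damped* frequency `fd = fn·√(1−ζ²)`.
The bedside rule is reported as-is by default; `correct_damping=True`
applies the correction, and is required to recover the true natural
frequency within 0.5 Hz at damping ≥0.2 (at ζ = 0.29 the uncorrected
reading is ≈4% low by construction). QC ranges are configuration, with the
observed system ranges (15–29 Hz, 0.14–0.29, inclusive) as defaults.

## Oscillometric processing

The deflation segment is the longest run (brief sub-second interruptions
closed) where the 2-s-smoothed pressure falls faster than 1 mmHg/s,
required to span ≥60 mmHg. The ramp is a Huber-robust line
(`statsmodels.RLM`), re-centred so the pulsatile residual has exactly zero
mean; raw = ramp + pulsatile on the segment by construction.

Pulses are peaks of the 12-Hz band-limited pulsatile signal (minimum
distance 0.6 of the autocorrelation-estimated period, prominence
0.1 mmHg); feet are the minima between peaks. Per-pulse amplitude is the
noise-floor-corrected RMS of the 6-Hz band-limited cycle, scaled per
recording to peak-to-peak units — an estimator of "pulse max − pulse min"
that pools the whole cycle and sits near the matched-filter noise bound.
The cuff pressure attached to a pulse is ramp + band-limited pulsatile at
its foot (i.e. the actual cuff level at that instant).

Envelope pressures: amplitudes are smoothed by a 5-pulse moving average;
MAP is the vertex of a concave quadratic fitted to log-amplitude over the
points within 50% of the peak (exact for a Gaussian envelope, and a
second-order approximation for any smooth unimodal one); SBP and DBP are
the linear-interpolated cuff pressures where the envelope falls to the
characteristic ratios, defaults 0.55 (systolic, above MAP) and 0.70
(diastolic, below MAP) — mid-range of published oscillometric practice
and configurable, since no disclosed values exist. A monotone envelope
(no interior maximum) is an error: the cuff range did not bracket MAP.

The residuum score reconstructs the expected pulsatile signal from the
amplitude-normalised mean pulse scaled to each cycle, and takes the RMS of
the leftover per 2-s window; windows above 1.5 mmHg are flagged and a
recording with more than 30% flagged windows is flagged as a whole
(mirroring the invasive arrhythmia fraction). The thresholds are
configuration; nothing published constrains them.

Central estimation: the ensemble pulse is the amplitude-normalised mean of
pulses recorded within ±15 mmHg of envelope MAP, affinely calibrated so
its minimum equals brachial DBP and its time-average equals brachial MAP
(the calibration-as-preprocessing step). The default surrogate estimator
sets cDBP and cMAP to the calibrated values and
`cSBP = MAP + α·(calibrated max − MAP)` with α = 0.8 (a single
pulse-pressure de-amplification factor). It is a transparent placeholder
for proprietary device transforms, which are not public and not in scope;
alternative estimators register under the same contract
(`register_estimator`). In cohort runs the default `estimator="recorded"`
uses the device estimates carried in the data (as a real validation study
does), falling back to the surrogate chain when none exist.

## Agreement and grading

Sample SDs use n−1 throughout. Limits of agreement are mean ± 1.96·SD
(asserted as an identity on every result). Pearson r is computed on the
paired values; the trend line regresses estimated on invasive, and the
slope of difference against pair mean is also reported for Bland–Altman
plots. Error bins count |error| strictly below 5/10/15 mmHg, cumulatively;
reported percentages are rounded to one decimal but grading uses the
unrounded values, with the rounded-percentage grade reported alongside
and any disagreement flagged (a cohort at 84.8% unrounded vs the 85%
grade-A threshold is exactly the case where the two differ). The 2018
AAMI/ESH/ISO criterion uses the normal model for P(|error| ≤ 10 mmHg)
with the empirical fraction available alongside; SD = 0 is treated as a
point mass. Range-conformity rows partition the cohort (the ≥140 and ≥85
rows exclude their extreme top rows, matching how such tables are
tallied), and the recruitment ratio is 100·n/85 rounded to a whole
percent.

## Problem sizes and determinism

All randomness flows from `numpy.random.default_rng` seeded per call;
identical seeds give bit-identical signals and reports. The test suite
and the acceptance script use cohorts of up to 191 patients with
site-faithful sampling rates and durations (240/500/2000 Hz, 20–90 s),
200-recording envelope sweeps, and 1,000-instance brute-force oracle
comparisons; a full study run takes a few seconds on one CPU.

## Known limitations

* The surrogate central estimator is not a model of any real transform;
  cohort-level agreement statistics are meaningful only under the
  injected device-error model.
* Reference extreme-value biases (SBP high, DBP low by ~1–2 mmHg under
  default noise) propagate into cohort mean differences for those
  components; MAP is unbiased by construction.
* Foot timing under noise is limited by the flat diastolic tail; timing
  oracles are therefore verified on noise-free signals, and noisy-signal
  behaviour is covered via beat counts and value recovery instead.
* No R-peak synchronisation between channels: agreement compares
  recording-level averages, which is the hemodynamic-stability rationale
  for the SD exclusion limits.
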