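# cbpval

Validation pipeline for cuff-based **central blood pressure (cBP)**
estimators against an invasive aortic reference, with a synthetic-data
module that makes the whole pipeline testable without access to
catheter-lab recordings.

Central (aortic) pressure differs from brachial cuff pressure and predicts
hypertensive organ damage better. Devices that estimate absolute cBP from
an oscillometric upper-arm cuff ("type II" devices) are validated
invasively: a fluid-filled catheter records aortic pressure while the cuff
records simultaneously, and the device estimate is compared against the
per-beat-averaged invasive reference under the ARTERY 2017, ANSI/AAMI/ISO
81060-2:2013, AAMI/ESH/ISO 2018 and BHS protocols. `cbpval` implements
that whole methodology as a reusable, tested pipeline:

* **`synthcohort`** — analytic generators: invasive beat trains with known
  per-beat SBP/DBP/MAP, extrasystoles and slow instability; cuff-deflation
  recordings with a Gaussian oscillometric envelope peaking at MAP; damped
  flush tests; full paired cohorts with a configurable device-error model.
* **`invasive`** — beat-foot detection, per-beat values (SBP = wave peak,
  DBP = lowest point, MAP = area under the curve over the beat), automated
  outlier clearing (median ± k·robust-SD), recording summary, and the
  exclusion rules: beat-to-beat SD above 10/6/6 mmHg (SBP/MAP/DBP) or more
  than 30% of beats cleared (severe arrhythmia).
* **`catheterqc`** — catheter frequency response from a fast-flush test:
  natural frequency from the time between the 2nd and 3rd oscillation,
  damping coefficient from their amplitude ratio via the logarithmic
  decrement, checked against acceptance ranges (defaults 15–29 Hz,
  0.14–0.29).
* **`oscillo`** — deflation-ramp separation, pulse and foot-point
  detection, envelope blood pressures via characteristic ratios, a
  residuum artifact score, and MAP/DBP-calibrated ensemble pulses fed to a
  **pluggable central estimator** (the built-in surrogate is deliberately
  simple and clearly labelled; proprietary device transforms are out of
  scope).
* **`agreement`** — Bland–Altman statistics (difference = invasive −
  estimated, limits of agreement mean ± 1.96 SD), error bins
  (<5/<10/<15 mmHg), the 2018 AAMI/ESH/ISO tolerable-error probability
  `100·[Φ((10−μ)/σ) − Φ((−10−μ)/σ)]`, ARTERY/AAMI pass rules, BHS grading
  and ARTERY range-conformity tables.
* **`runner`** — end-to-end orchestration from a cohort manifest to a
  machine-readable study report (JSON + tidy CSVs + Bland–Altman plot
  data), with per-patient exclusion accounting.

## Worked example

Simulate a 20-patient paired cohort (10% with severe arrhythmia) and run
the full validation:

```sh
cbpval simulate --n 20 --seed 7 --arrhythmia-fraction 0.1 --out demo/cohort
cbpval analyze --manifest demo/cohort/manifest.csv --out demo/results
```

which prints

```
analyzed 18 of 20 patients
SBP: mean diff +0.11 mmHg, SD 5.30 mmHg
MAP: mean diff +0.11 mmHg, SD 3.09 mmHg
DBP: mean diff +0.15 mmHg, SD 4.14 mmHg
```

The two arrhythmic patients were excluded (more than 30% of their beats
cleared), and the remaining 18 paired measurements agree with a mean
invasive-minus-estimated difference of +0.11 mmHg and SD 5.30 mmHg for
systolic cBP — inside the ARTERY band (|mean| < 5, SD < 8 mmHg).
`demo/results/report.json` holds the full study report; the grading block
shows BHS grade A for all three components and a 94.1% modelled
probability of a tolerable (≤10 mmHg) systolic error, passing the 2018
AAMI/ESH/ISO ≥85% criterion.

The same run is available from Python:

```python
from cbpval import CohortSpec, StudyConfig, analyze_cohort, synth_cohort

cohort = synth_cohort(CohortSpec(n_patients=20, arrhythmia_fraction=0.1,
                                 rng_seed=7))
report = analyze_cohort(cohort, StudyConfig())
print(report.agreement["SBP"].mean_diff, report.grading["SBP"].bhs_grade)
```

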