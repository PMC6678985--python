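"""Agreement statistics and protocol grading for paired central pressures.

Differences are always invasive minus estimated, so a positive mean means
the device underestimates. Limits of agreement are mean +/- 1.96 * SD with
the sample SD (n-1). Error-distribution bins count |error| strictly below
5 / 10 / 15 mmHg (cumulative). Protocol verdicts:

* ARTERY 2017: |mean| < 5 mmHg and SD < 8 mmHg (strict).
* AAMI 2013 (81060-2): |mean| <= 5 mmHg and SD <= 8 mmHg.
* AAMI/ESH/ISO 2018: estimated probability of a tolerable error
  (|error| <= 10 mmHg) of at least 85%, under a normal model for the
  differences; the empirical fraction is reported alongside.
* BHS: best grade whose cumulative bin percentages meet all three
  thresholds (A: >=60/85/95, B: >=50/75/90, C: >=40/65/85, else D),
  evaluated on unrounded percentages; the grade from one-decimal rounded
  percentages is reported too and any disagreement flagged.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import AgreementResult, GradingResult

BIN_EDGES = (5.0, 10.0, 15.0)
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0),
                  "B": (50.0, 75.0, 90.0),
                  "C": (40.0, 65.0, 85.0)}
ARTERY_SAMPLE_GOAL = 85  # minimum cohort size the recruitment ratio refers to


def error_bins(diffs):
    """Cumulative counts and percentages of |error| < 5 / 10 / 15 mmHg.

    Returns ``(counts, pct, pct_rounded)``; percentages are 100*count/n,
    unrounded and rounded to one decimal for reporting.
    """
    d = np.abs(np.asarray(diffs, float))
    if d.size == 0:
        raise ValueError("need at least one error value")
    counts = tuple(int((d < edge).sum()) for edge in BIN_EDGES)
    pct = tuple(100.0 * c / d.size for c in counts)
    return counts, pct, tuple(round(p, 1) for p in pct)


def bland_altman(invasive, estimated, component: str = "SBP") -> AgreementResult:
    """Bland-Altman agreement of device estimates against invasive values.

    ``diff = invasive - estimated``; r is the Pearson correlation of the
    paired values; the trend line regresses estimated on invasive, and the
    slope of difference against pair mean is reported for the
    Bland-Altman plot.
    """
    inv = np.asarray(invasive, float)
    est = np.asarray(estimated, float)
    if inv.shape != est.shape or inv.ndim != 1:
        raise ValueError("invasive and estimated must be 1-D of equal length")
    n = inv.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = inv - est
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa = (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)

    r_defined = inv.std() > 0 and est.std() > 0
    if r_defined:
        r = float(stats.pearsonr(inv, est).statistic)
        slope, intercept = (float(v) for v in np.polyfit(inv, est, 1))
    else:
        r, slope, intercept = float("nan"), float("nan"), float("nan")
    means = (inv + est) / 2.0
    if means.std() > 0:
        ba_slope, ba_intercept = (float(v) for v in np.polyfit(means, diffs, 1))
    else:
        ba_slope, ba_intercept = float("nan"), float(mean_diff)

    counts, pct, pct_rounded = error_bins(diffs)
    return AgreementResult(
        component=component, n=n, mean_diff=mean_diff, sd_diff=sd_diff,
        loa_lower=float(loa[0]), loa_upper=float(loa[1]),
        r=r, r_squared=r * r if r_defined else float("nan"),
        slope=slope, intercept=intercept,
        ba_slope=ba_slope, ba_intercept=ba_intercept,
        bin_counts=counts, bin_pct=pct, bin_pct_rounded=pct_rounded,
        r_defined=bool(r_defined))


def iso2018_probability(mean_diff: float, sd_diff: float,
                        limit: float = 10.0) -> float:
    """Percent probability of a tolerable error (|error| <= limit) under a
    normal model N(mean_diff, sd_diff^2). SD of zero is a point mass."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    if sd_diff == 0:
        return 100.0 if abs(mean_diff) <= limit else 0.0
    z_hi = (limit - mean_diff) / sd_diff
    z_lo = (-limit - mean_diff) / sd_diff
    return float(100.0 * (stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)))


def empirical_tolerable_fraction(diffs, limit: float = 10.0) -> float:
    """Percent of observed |errors| <= limit (the model-free counterpart)."""
    d = np.abs(np.asarray(diffs, float))
    return float(100.0 * (d <= limit).mean())


def bhs_grade(p5: float, p10: float, p15: float) -> str:
    """Best BHS grade whose three cumulative thresholds are all met."""
    for g, (t5, t10, t15) in BHS_THRESHOLDS.items():
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            return g
    return "D"


def grade(result: AgreementResult) -> GradingResult:
    """Protocol verdicts for one component's agreement result."""
    mean, sd = result.mean_diff, result.sd_diff
    prob = iso2018_probability(mean, sd)
    g_unrounded = bhs_grade(*result.bin_pct)
    g_rounded = bhs_grade(*result.bin_pct_rounded)
    return GradingResult(
        component=result.component,
        artery_pass=bool(abs(mean) < 5.0 and sd < 8.0),
        aami2013_pass=bool(abs(mean) <= 5.0 and sd <= 8.0),
        iso2018_prob=prob,
        iso2018_pass=bool(prob >= 85.0),
        bhs_grade=g_unrounded,
        bhs_grade_rounded=g_rounded,
        bhs_rounding_disagrees=bool(g_unrounded != g_rounded))


#: pressure-range rows: (label, predicate, goal percent or None)
_SBP_RANGES = (
    ("cSBP <= 100", lambda v: v <= 100.0, 5.0),
    ("cSBP > 100 < 140", lambda v: (v > 100.0) & (v < 140.0), None),
    ("cSBP >= 140", lambda v: (v >= 140.0) & (v < 160.0), 20.0),
    ("cSBP >= 160", lambda v: v >= 160.0, 5.0),
)
_DBP_RANGES = (
    ("cDBP <= 60", lambda v: v <= 60.0, 5.0),
    ("cDBP > 60 < 85", lambda v: (v > 60.0) & (v < 85.0), None),
    ("cDBP >= 85", lambda v: (v >= 85.0) & (v < 100.0), 20.0),
    ("cDBP >= 100", lambda v: v >= 100.0, 5.0),
)


def range_conformity(values, component: str = "SBP"):
    """Distribution of invasive pressures over the recommended ranges.

    Rows partition the cohort (the >=140 / >=85 rows exclude the extreme
    top row, matching how such tables are tallied); percentages to one
    decimal. Returns ``(rows, recruitment_ratio_pct)`` where rows are dicts
    with label / count / pct / goal_pct and the recruitment ratio is
    100*n/85 rounded to a whole percent.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("need at least one value")
    spec = {"SBP": _SBP_RANGES, "DBP": _DBP_RANGES}.get(component.upper())
    if spec is None:
        raise ValueError("range conformity is defined for SBP and DBP")
    rows = []
    for label, pred, goal in spec:
        count = int(np.count_nonzero(pred(v)))
        rows.append({"label": label, "count": count,
                     "pct": round(100.0 * count / v.size, 1),
                     "goal_pct": goal})
    ratio = int(round(100.0 * v.size / ARTERY_SAMPLE_GOAL))
    return rows, ratio
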