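"""Synthetic paired-recording generator for the validation pipeline.

The catheter-lab data this pipeline was designed around are not public, so
everything the pipeline consumes is generated here with analytic ground
truth: invasive aortic beat trains, oscillometric cuff-deflation recordings,
catheter flush tests, and full paired cohorts with a known device-error
model.

Beat morphology
---------------
Each beat is a piecewise analytic pulse on the unit interval:

* a raised-cosine systolic upstroke on [0, a] rising from 0 to 1,
* a time-warped raised-cosine diastolic relaxation
  ``0.5 * (1 + cos(pi * u**p))`` on [a, 1], falling from 1 back to exactly 0
  with zero slope at the landing (so the sampled minimum attains the foot
  pressure at any sampling rate),
* an optional raised-cosine dicrotic notch subtracted during early diastole.

The warp exponent ``p`` is the single free shape parameter; it is solved
numerically (via a precomputed monotone mean table) so the time-average of
the beat equals the requested MAP. The attainable MAP fraction
``(map - dbp)/(sbp - dbp)`` is the open interval ``(a/2, 1 - a/2)``;
anything outside raises a parameter error.

All randomness flows from one ``numpy.random.Generator`` seeded per call,
so identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import PressureWaveform

# ---------------------------------------------------------------------------
# beat shape


@dataclass
class BeatShapeParams:
    """Target per-beat pressures plus beat-to-beat variability.

    ``sbp_sd``/``dbp_sd``/``map_frac_sd`` set the beat-to-beat scatter of the
    per-beat targets; the defaults reproduce the beat-to-beat standard
    deviations observed invasively in stable patients (about 4.1 / 2.3 mmHg
    for SBP / DBP and ~2.8 mmHg for MAP).
    """

    sbp: float
    dbp: float
    map_target: float
    heart_rate: float
    notch_depth: float = 0.10
    rng_seed: int = 0
    # beat-to-beat variability (standard deviations)
    sbp_sd: float = 4.08
    dbp_sd: float = 2.31
    map_frac_sd: float = 0.025
    hr_jitter_frac: float = 0.02
    # measurement model
    noise_sd: float = 0.5
    # morphology
    upstroke_frac: float = 0.20
    ectopic_pp_drop: float | tuple = 0.25
    ectopic_interval_frac: float = 0.60
    ectopic_pause_frac: float = 1.0  # 1.0 = interpolated (no pause)
    # slow coherent level drift (hemodynamic instability), mmHg and seconds
    drift_amp: float = 0.0
    drift_period_s: float = 10.0

    def __post_init__(self) -> None:
        if not (self.dbp < self.map_target < self.sbp):
            raise ValueError("require dbp < map_target < sbp")
        if not (30.0 <= self.heart_rate <= 180.0):
            raise ValueError("heart_rate must lie in [30, 180] /min")
        if not (0.0 <= self.notch_depth <= 0.5):
            raise ValueError("notch_depth must lie in [0, 0.5]")


def _notch_window(u: np.ndarray, a: float) -> np.ndarray:
    """Unit raised-cosine dip centred in early diastole (0..1 amplitude)."""
    centre = a + 0.35 * (1.0 - a)
    width = 0.20 * (1.0 - a)
    x = (u - centre) / (width / 2.0)
    out = np.zeros_like(u)
    m = np.abs(x) < 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * x[m]))
    return out


def _decay(ud, p: float):
    """Diastolic relaxation on normalised diastole ud in [0, 1]."""
    return 0.5 * (1.0 + np.cos(np.pi * np.power(ud, p)))


# monotone table p -> mean of the relaxation, built once at import
_P_GRID = np.logspace(-2.5, 2.5, 600)
_UD = np.linspace(0.0, 1.0, 4001)
_MEAN_GRID = np.array([np.trapezoid(_decay(_UD, p), _UD) for p in _P_GRID])


def _decay_mean(p: float) -> float:
    return float(np.interp(p, _P_GRID, _MEAN_GRID))


def _effective_notch_depth(k: float, a: float, depth: float) -> float:
    """Cap the notch so the pulse stays inside [0, 1]."""
    if depth <= 0:
        return 0.0
    decay_at_centre = float(_decay(0.35, k))
    return float(min(depth, 0.8 * decay_at_centre))


def _unit_pulse(u: np.ndarray, k: float, a: float, notch_depth: float) -> np.ndarray:
    """Analytic beat shape on [0, 1): min 0 (at both ends), max 1 (at u=a)."""
    u = np.asarray(u, dtype=float)
    p = np.empty_like(u)
    sys = u < a
    p[sys] = 0.5 * (1.0 - np.cos(np.pi * u[sys] / a))
    ud = (u[~sys] - a) / (1.0 - a)
    p[~sys] = _decay(ud, k)
    d = _effective_notch_depth(k, a, notch_depth)
    if d > 0:
        p = p - d * _notch_window(u, a)
    return p


def _pulse_mean(k: float, a: float, notch_depth: float) -> float:
    """Time-average of the unit pulse (tabulated decay mean)."""
    d = _effective_notch_depth(k, a, notch_depth)
    return (a / 2.0 + (1.0 - a) * _decay_mean(k)
            - d * 0.20 * (1.0 - a) / 2.0)


def solve_shape_exponent(map_frac: float, a: float = 0.20,
                         notch_depth: float = 0.10) -> float:
    """Solve the diastolic exponent so the beat mean hits ``map_frac``.

    ``map_frac`` is (map - dbp) / (sbp - dbp). Raises ``ValueError`` when the
    requested mean is outside the attainable range of the shape family.
    """
    k_lo, k_hi = float(_P_GRID[0]), float(_P_GRID[-1])
    lo, hi = _pulse_mean(k_lo, a, notch_depth), _pulse_mean(k_hi, a, notch_depth)
    if not (lo < map_frac < hi):
        raise ValueError(
            f"map_target infeasible for this morphology: MAP fraction "
            f"{map_frac:.3f} outside attainable ({lo:.3f}, {hi:.3f})"
        )
    return float(brentq(lambda k: _pulse_mean(k, a, notch_depth) - map_frac,
                        k_lo, k_hi, xtol=1e-10))


def _beat_mean(k: float, n0: float, s: float, n1: float, a: float,
               notch_depth: float) -> float:
    """Time-average of a beat rising from foot pressure ``n0`` to ``s`` and
    relaxing to the next foot pressure ``n1``."""
    d = _effective_notch_depth(k, a, notch_depth)
    up = a * (n0 + s) / 2.0
    decay = (1.0 - a) * (n1 + (s - n1) * _decay_mean(k))
    notch = d * (s - n1) * 0.20 * (1.0 - a) / 2.0
    return up + decay - notch


def _solve_beat_exponent(n0: float, s: float, n1: float, map_target: float,
                         a: float, notch_depth: float):
    """Exponent hitting ``map_target`` for a beat between foot pressures
    ``n0`` and ``n1``; the target is clipped into the attainable interval."""
    k_lo, k_hi = float(_P_GRID[0]), float(_P_GRID[-1])
    lo = _beat_mean(k_lo, n0, s, n1, a, notch_depth)
    hi = _beat_mean(k_hi, n0, s, n1, a, notch_depth)
    margin = 0.02 * (hi - lo)
    target = float(np.clip(map_target, lo + margin, hi - margin))
    k = float(brentq(
        lambda kk: _beat_mean(kk, n0, s, n1, a, notch_depth) - target,
        k_lo, k_hi, xtol=1e-10))
    return k, target


def _render_beat(u: np.ndarray, k: float, n0: float, s: float, n1: float,
                 a: float, notch_depth: float) -> np.ndarray:
    """Evaluate the beat on normalised time ``u`` in [0, 1)."""
    u = np.asarray(u, dtype=float)
    p = np.empty_like(u)
    sys = u < a
    p[sys] = n0 + (s - n0) * 0.5 * (1.0 - np.cos(np.pi * u[sys] / a))
    ud = (u[~sys] - a) / (1.0 - a)
    p[~sys] = n1 + (s - n1) * _decay(ud, k)
    d = _effective_notch_depth(k, a, notch_depth)
    if d > 0:
        p = p - d * (s - n1) * _notch_window(u, a)
    return p


# ---------------------------------------------------------------------------
# invasive beat train


def _draw_beat_table(shape: BeatShapeParams, duration: float,
                     ectopic_rate: float, rng: np.random.Generator,
                     exact_ectopic_count: bool) -> pd.DataFrame:
    """Draw per-beat targets until the cumulative time exceeds ``duration``.

    Beat-to-beat variability is AR(1)-correlated (lag-1 correlation 0.6),
    mimicking respiratory modulation, and foot pressures are shared between
    consecutive beats so the rendered signal is continuous at every foot.
    The table is independent of the sampling rate, so the same seed yields
    the same physiology at 240, 500 or 2000 Hz.
    """
    base_period = 60.0 / shape.heart_rate
    n_est = int(math.ceil(duration / base_period)) + 4
    rho = 0.6

    def _ar1(n, sd):
        innov = math.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
        e = np.empty(n)
        e[0] = rng.standard_normal()
        for i in range(1, n):
            e[i] = rho * e[i - 1] + innov[i]
        return sd * e

    periods = base_period * (1.0 + shape.hr_jitter_frac * rng.standard_normal(n_est))
    sbp = shape.sbp + _ar1(n_est, shape.sbp_sd)
    foot = shape.dbp + _ar1(n_est + 1, shape.dbp_sd)
    base_frac = (shape.map_target - shape.dbp) / (shape.sbp - shape.dbp)
    frac = np.clip(base_frac + shape.map_frac_sd * rng.standard_normal(n_est),
                   0.20, 0.65)

    if exact_ectopic_count:
        # place the exact count among beats certain to fit the recording,
        # so the realised ectopic fraction is not diluted by the tail
        m = max(2, n_est - 5)
        n_ect = int(round(ectopic_rate * m))
        ectopic = np.zeros(n_est, bool)
        if n_ect:
            ectopic[rng.choice(m, size=n_ect, replace=False)] = True
    else:
        ectopic = rng.random(n_est) < ectopic_rate

    drop = shape.ectopic_pp_drop
    for i in np.flatnonzero(ectopic):
        d = rng.uniform(*drop) if isinstance(drop, tuple) else float(drop)
        sbp[i] = foot[i] + (1.0 - d) * (sbp[i] - foot[i])
        periods[i] *= shape.ectopic_interval_frac
        if (shape.ectopic_pause_frac != 1.0 and i + 1 < n_est
                and not ectopic[i + 1]):  # optional compensatory pause
            periods[i + 1] *= shape.ectopic_pause_frac

    # keep every beat physiologic after jitter
    sbp = np.maximum(sbp, foot[:-1] + 5.0)

    t_foot = np.concatenate([[0.0], np.cumsum(periods)[:-1]])

    if shape.drift_amp > 0:
        # coherent slow drift: shifts feet, systolic peaks and MAP together,
        # leaving pulse pressure and morphology untouched
        phase = rng.uniform(0.0, 2.0 * math.pi)
        t_nodes = np.concatenate([t_foot, [t_foot[-1] + periods[-1]]])
        drift_nodes = shape.drift_amp * np.sin(
            2.0 * math.pi * t_nodes / shape.drift_period_s + phase)
        foot = foot + drift_nodes
        sbp = sbp + drift_nodes[:-1]

    keep = t_foot + periods <= duration + 1e-12
    df = pd.DataFrame({
        "t_foot": t_foot[keep],
        "period": periods[keep],
        "sbp": sbp[keep],
        "foot_pressure": foot[:-1][keep],
        "next_foot_pressure": foot[1:][keep],
        "map": foot[:-1][keep] + frac[keep] * (sbp - foot[:-1])[keep],
        "ectopic": ectopic[keep],
    })
    if len(df) < 2:
        raise ValueError("duration must cover at least 2 beats")
    return df


def synth_aortic_waveform(shape: BeatShapeParams, duration: float,
                          sampling_rate: float, ectopic_rate: float = 0.0,
                          *, exact_ectopic_count: bool = False):
    """Render an invasive aortic pressure waveform plus ground truth.

    Returns ``(waveform, truth)`` where ``truth`` is a DataFrame with one row
    per complete beat: foot time, period, per-beat SBP/DBP/MAP and an ectopic
    label. Within each beat the rendered signal attains the tabulated SBP and
    DBP exactly (up to sample quantisation) and its time-average equals the
    tabulated MAP by construction of the shape exponent.
    """
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be at least 100 Hz")
    if duration < 2 * 60.0 / shape.heart_rate:
        raise ValueError("duration must cover at least 2 beats")
    # validate feasibility of the nominal morphology before any drawing
    solve_shape_exponent(
        (shape.map_target - shape.dbp) / (shape.sbp - shape.dbp),
        shape.upstroke_frac, shape.notch_depth)

    rng = np.random.default_rng(shape.rng_seed)
    truth = _draw_beat_table(shape, duration, ectopic_rate, rng,
                             exact_ectopic_count)

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    p = np.empty(n, dtype=float)
    p.fill(truth["next_foot_pressure"].iloc[-1])

    a = shape.upstroke_frac
    maps, dbps = [], []
    for row in truth.itertuples():
        k, map_actual = _solve_beat_exponent(
            row.foot_pressure, row.sbp, row.next_foot_pressure, row.map,
            a, shape.notch_depth)
        maps.append(map_actual)
        dbps.append(min(row.foot_pressure, row.next_foot_pressure))
        i0 = int(np.ceil(row.t_foot * sampling_rate - 1e-9))
        i1 = min(int(np.ceil((row.t_foot + row.period) * sampling_rate - 1e-9)), n)
        u = (t[i0:i1] - row.t_foot) / row.period
        p[i0:i1] = _render_beat(u, k, row.foot_pressure, row.sbp,
                                row.next_foot_pressure, a, shape.notch_depth)
    truth = truth.assign(map=np.array(maps), dbp=np.array(dbps))
    # render the trailing partial beat so detectors see a realistic tail
    t_tail = truth["t_foot"].iloc[-1] + truth["period"].iloc[-1]
    i0 = int(np.ceil(t_tail * sampling_rate - 1e-9))
    if i0 < n:
        row = truth.iloc[-1]
        k, _ = _solve_beat_exponent(
            row["next_foot_pressure"], row["sbp"], row["next_foot_pressure"],
            row["map"], a, shape.notch_depth)
        u = np.clip((t[i0:] - t_tail) / row["period"], 0.0, 1.0 - 1e-9)
        p[i0:] = _render_beat(u, k, row["next_foot_pressure"], row["sbp"],
                              row["next_foot_pressure"], a, shape.notch_depth)

    if shape.noise_sd > 0:
        p = p + shape.noise_sd * rng.standard_normal(n)

    wf = PressureWaveform(p, sampling_rate, channel="invasive")
    return wf, truth


# ---------------------------------------------------------------------------
# oscillometric cuff recording


def synth_cuff_recording(true_bp, heart_rate: float, deflation_rate: float = 4.0,
                         sampling_rate: float = 500.0, *,
                         start_pressure: float | None = None,
                         end_pressure: float | None = None,
                         peak_amplitude: float = 3.0,
                         envelope_width: float = 25.0,
                         noise_sd: float = 0.5,
                         rng_seed: int = 0):
    """Simulate a linear cuff deflation with a superimposed pulse envelope.

    ``true_bp`` is the (sbp, map, dbp) triple of the brachial pressures the
    cuff sees. Pulse amplitudes follow a Gaussian envelope in cuff-minus-MAP
    pressure (width ``envelope_width`` mmHg) whose maximum sits exactly where
    the cuff passes MAP. Returns ``(waveform, truth)`` with foot times,
    per-pulse amplitudes and cuff pressures in the truth dict.
    """
    sbp, map_, dbp = (float(x) for x in true_bp)
    if not (dbp < map_ < sbp):
        raise ValueError("true_bp must satisfy dbp < map < sbp")
    if deflation_rate <= 0:
        raise ValueError("deflation_rate must be positive")
    if sampling_rate < 8.0 * heart_rate / 60.0:
        raise ValueError("sampling_rate too low to resolve pulses")
    if start_pressure is None:
        start_pressure = sbp + 40.0
    if start_pressure <= sbp + 30.0:
        raise ValueError("deflation must start > sbp + 30 mmHg")
    if end_pressure is None:
        end_pressure = max(dbp - 35.0, 20.0)

    rng = np.random.default_rng(rng_seed)
    duration = (start_pressure - end_pressure) / deflation_rate
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    ramp = start_pressure - deflation_rate * t

    period = 60.0 / heart_rate
    feet, amps, cuffs = [], [], []
    pulsatile = np.zeros(n)
    a = 0.20
    k = solve_shape_exponent(0.40, a, 0.10)
    t_f = rng.uniform(0.0, period)  # random phase of the first pulse
    while t_f + period < duration:
        per = period * (1.0 + 0.02 * rng.standard_normal())
        cuff_at_foot = start_pressure - deflation_rate * t_f
        amp = peak_amplitude * math.exp(-((cuff_at_foot - map_) ** 2)
                                        / (2.0 * envelope_width ** 2))
        i0 = int(np.ceil(t_f * sampling_rate - 1e-9))
        i1 = min(int(np.ceil((t_f + per) * sampling_rate - 1e-9)), n)
        u = (t[i0:i1] - t_f) / per
        pulsatile[i0:i1] = amp * _unit_pulse(u, k, a, 0.10)
        feet.append(t_f)
        amps.append(amp)
        cuffs.append(cuff_at_foot)
        t_f += per

    raw = ramp + pulsatile
    if noise_sd > 0:
        raw = raw + noise_sd * rng.standard_normal(n)

    wf = PressureWaveform(raw, sampling_rate, channel="cuff")
    truth = {
        "true_bp": (sbp, map_, dbp),
        "deflation_rate": deflation_rate,
        "start_pressure": start_pressure,
        "foot_times": np.array(feet),
        "amplitudes": np.array(amps),
        "cuff_at_foot": np.array(cuffs),
        "heart_rate": heart_rate,
    }
    return wf, truth


# ---------------------------------------------------------------------------
# catheter flush test


@dataclass
class FlushSpec:
    """Second-order response of a fluid-filled catheter-transducer system."""

    natural_frequency: float
    damping_coefficient: float
    baseline_pressure: float = 80.0
    flush_amplitude: float = 200.0
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.damping_coefficient < 1.0):
            raise ValueError("damping coefficient must lie in (0, 1): "
                             "no oscillation otherwise")
        if self.flush_amplitude < 180.0:
            raise ValueError("flush pulse must reach at least 180 mmHg")
        if self.sampling_rate <= 10.0 * self.natural_frequency:
            raise ValueError("sampling_rate must exceed 10 x natural_frequency")


def synth_flush_test(spec: FlushSpec, duration: float = 2.0,
                     *, pre_release: float = 0.5,
                     noise_sd: float = 0.0, rng_seed: int = 0) -> PressureWaveform:
    """Square flush pulse followed by a damped free oscillation.

    After the release at ``pre_release`` seconds the signal is
    ``baseline + A exp(-zeta*wn*t) cos(wd*t)`` with ``wn = 2 pi fn`` and
    ``wd = wn sqrt(1 - zeta^2)``; the ground truth fn and zeta are the spec's.
    """
    zeta = spec.damping_coefficient
    wn = 2.0 * math.pi * spec.natural_frequency
    wd = wn * math.sqrt(1.0 - zeta ** 2)
    post = duration - pre_release
    if post < 4.0 * 2.0 * math.pi / wd:
        raise ValueError("duration must cover at least 4 oscillation cycles")

    fs = spec.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    p = np.full(n, spec.baseline_pressure + spec.flush_amplitude)
    mask = t >= pre_release
    tau = t[mask] - pre_release
    p[mask] = spec.baseline_pressure + spec.flush_amplitude * np.exp(
        -zeta * wn * tau) * np.cos(wd * tau)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        p = p + noise_sd * rng.standard_normal(n)
    return PressureWaveform(p, fs, channel="flush")


# ---------------------------------------------------------------------------
# full cohort


#: Cohort pressure distributions: invasive central values of the reference
#: population (mean, SD in mmHg) and the brachial offsets the cuff sees.
DEFAULT_BP_MEANS_SDS = {
    "sbp": (145.1, 24.0),
    "map": (101.5, 14.8),
    "dbp": (72.1, 12.2),
}
#: Device-error model per component: distribution of invasive - estimated
#: differences (mean, SD in mmHg).
DEFAULT_DEVICE_ERROR = {
    "sbp": (0.71, 5.95),
    "map": (0.19, 3.78),
    "dbp": (2.96, 5.21),
}
#: Mean brachial-minus-central offsets (pulse-pressure amplification at the
#: arm) matching the cohort's non-invasive brachial means.
BRACHIAL_OFFSETS = {"sbp": 4.5, "map": 5.9, "dbp": 13.0}

#: site name -> (invasive sampling rate Hz, recording duration s, share)
SITE_PROFILES = {
    "bad_berka": (240.0, 90.0, 63 / 145),
    "bad_oeynhausen": (2000.0, 90.0, 50 / 145),
    "greifswald": (500.0, 20.0, 32 / 145),
}


@dataclass
class CohortSpec:
    """Study-population recipe for a paired synthetic cohort."""

    n_patients: int = 145
    bp_means_sds: dict = field(default_factory=lambda: dict(DEFAULT_BP_MEANS_SDS))
    hr_mean_sd: tuple = (69.0, 12.2)
    device_error: dict = field(default_factory=lambda: dict(DEFAULT_DEVICE_ERROR))
    arrhythmia_fraction: float = 0.0
    unstable_fraction: float = 0.0
    corrupt_fraction: float = 0.0
    rng_seed: int = 0
    sbp_dbp_corr: float = 0.6
    min_pulse_pressure: float = 30.0
    noise_sd: float = 0.5
    clean_ectopic_rate: float = 0.02
    # severe-arrhythmia emulation: exact ectopic fraction and PP drop range
    arrhythmic_ectopic_rate: float = 0.40
    arrhythmic_pp_drop: tuple = (0.30, 0.50)
    unstable_drift_amp: float = 21.0
    site_profiles: dict = field(default_factory=lambda: dict(SITE_PROFILES))
    cuff_sampling_rate: float = 500.0
    include_flush: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for comp, (m, s) in self.bp_means_sds.items():
            if s < 0:
                raise ValueError(f"SD for {comp} must be >= 0")
        for frac in (self.arrhythmia_fraction, self.unstable_fraction,
                     self.corrupt_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("condition fractions must lie in [0, 1]")


@dataclass
class PatientRecord:
    """One simulated patient: paired signals plus full ground truth."""

    patient_id: str
    site: str
    condition: str  # clean | arrhythmic | unstable | corrupt
    invasive: PressureWaveform | None
    invasive_truth: pd.DataFrame | None
    cuff: PressureWaveform | None
    cuff_truth: dict | None
    flush: PressureWaveform | None
    flush_truth: dict | None
    true_central: tuple  # (csbp, cmap, cdbp)
    true_brachial: tuple
    device_estimate: tuple | None


def _draw_central_bp(spec: CohortSpec, rng: np.random.Generator) -> tuple:
    """Correlated SBP/DBP draw, redrawn until physiologically admissible."""
    m_s, s_s = spec.bp_means_sds["sbp"]
    m_d, s_d = spec.bp_means_sds["dbp"]
    rho = spec.sbp_dbp_corr
    for _ in range(1000):
        z1, z2 = rng.standard_normal(2)
        sbp = m_s + s_s * z1
        dbp = m_d + s_d * (rho * z1 + math.sqrt(1 - rho ** 2) * z2)
        if sbp - dbp >= spec.min_pulse_pressure and 40.0 <= dbp and sbp <= 240.0:
            break
    else:  # pragma: no cover - parameter pathology
        raise RuntimeError("could not draw admissible blood pressures")
    m_m = spec.bp_means_sds["map"][0]
    base_frac = (m_m - m_d) / (m_s - m_d)
    frac = float(np.clip(base_frac + 0.03 * rng.standard_normal(), 0.25, 0.60))
    map_ = dbp + frac * (sbp - dbp)
    return sbp, map_, dbp


def _assign_conditions(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_patients
    n_arr = int(round(spec.arrhythmia_fraction * n))
    n_uns = int(round(spec.unstable_fraction * n))
    n_cor = int(round(spec.corrupt_fraction * n))
    if n_arr + n_uns + n_cor > n:
        raise ValueError("condition fractions exceed cohort size")
    conditions = np.array(["clean"] * n, dtype=object)
    order = rng.permutation(n)
    conditions[order[:n_arr]] = "arrhythmic"
    conditions[order[n_arr:n_arr + n_uns]] = "unstable"
    conditions[order[n_arr + n_uns:n_arr + n_uns + n_cor]] = "corrupt"
    return conditions


def _assign_sites(spec: CohortSpec, rng: np.random.Generator) -> list:
    names = list(spec.site_profiles)
    shares = np.array([spec.site_profiles[s][2] for s in names], float)
    shares = shares / shares.sum()
    counts = np.floor(shares * spec.n_patients).astype(int)
    while counts.sum() < spec.n_patients:
        counts[int(np.argmax(shares * spec.n_patients - counts))] += 1
    sites = np.repeat(names, counts)
    return list(rng.permutation(sites))


def synth_cohort(spec: CohortSpec) -> list:
    """Generate a full paired cohort with a known device-error model.

    The device estimate is ``true_central - e`` with
    ``e ~ N(mean, sd)`` drawn per component from ``spec.device_error``, so a
    downstream Bland-Altman of invasive minus estimated recovers exactly
    those moments (up to sampling error).
    """
    rng = np.random.default_rng(spec.rng_seed)
    conditions = _assign_conditions(spec, rng)
    sites = _assign_sites(spec, rng)
    hr_m, hr_s = spec.hr_mean_sd

    patients = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        site = sites[i]
        cond = str(conditions[i])
        fs_inv, dur_inv, _ = spec.site_profiles[site]
        central = _draw_central_bp(spec, rng)
        brachial = tuple(
            c + BRACHIAL_OFFSETS[k] + 2.0 * rng.standard_normal()
            for c, k in zip(central, ("sbp", "map", "dbp")))
        if not (brachial[2] < brachial[1] < brachial[0]):
            brachial = (central[0] + 4.5, central[1] + 5.9, central[2] + 13.0)
        hr = float(np.clip(hr_m + hr_s * rng.standard_normal(), 36.0, 111.0))

        seed_inv, seed_cuff, seed_flush = (int(x) for x in
                                           rng.integers(0, 2 ** 31 - 1, size=3))

        shape = BeatShapeParams(
            sbp=central[0], dbp=central[2], map_target=central[1],
            heart_rate=hr, rng_seed=seed_inv, noise_sd=spec.noise_sd)
        if cond == "corrupt":
            # systematic acquisition failure: flatline with noise only
            n = int(round(dur_inv * fs_inv))
            flat = 100.0 + spec.noise_sd * np.random.default_rng(
                seed_inv).standard_normal(n)
            invasive, inv_truth = PressureWaveform(
                flat, fs_inv, channel="invasive"), None
        elif cond == "arrhythmic":
            shape = replace(shape, ectopic_pp_drop=spec.arrhythmic_pp_drop)
            invasive, inv_truth = synth_aortic_waveform(
                shape, dur_inv, fs_inv,
                ectopic_rate=spec.arrhythmic_ectopic_rate,
                exact_ectopic_count=True)
        elif cond == "unstable":
            shape = replace(shape, drift_amp=spec.unstable_drift_amp)
            invasive, inv_truth = synth_aortic_waveform(
                shape, dur_inv, fs_inv, ectopic_rate=spec.clean_ectopic_rate)
        else:
            invasive, inv_truth = synth_aortic_waveform(
                shape, dur_inv, fs_inv, ectopic_rate=spec.clean_ectopic_rate)

        cuff, cuff_truth = synth_cuff_recording(
            brachial, hr, sampling_rate=spec.cuff_sampling_rate,
            noise_sd=spec.noise_sd, rng_seed=seed_cuff)

        flush = flush_truth = None
        if spec.include_flush:
            frng = np.random.default_rng(seed_flush)
            fn = float(np.clip(21.9 + 3.0 * frng.standard_normal(), 16.5, 28.5))
            zeta = float(np.clip(0.21 + 0.03 * frng.standard_normal(),
                                 0.15, 0.28))
            flush = synth_flush_test(FlushSpec(fn, zeta), duration=2.0)
            flush_truth = {"natural_frequency": fn, "damping_coefficient": zeta}

        err = {k: rng.normal(m, s) for k, (m, s) in spec.device_error.items()}
        estimate = (central[0] - err["sbp"], central[1] - err["map"],
                    central[2] - err["dbp"])

        patients.append(PatientRecord(
            patient_id=pid, site=site, condition=cond,
            invasive=invasive, invasive_truth=inv_truth,
            cuff=cuff, cuff_truth=cuff_truth,
            flush=flush, flush_truth=flush_truth,
            true_central=central, true_brachial=brachial,
            device_estimate=estimate))
    return patients
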