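"""Oscillometric cuff-deflation processing.

The chain mirrors how a pulse-wave-analysis monitor works on the deflation
phase: fit and remove the linear cuff ramp, detect the superimposed pulses
and their foot points, build the amplitude envelope over cuff pressure,
read brachial MAP off the envelope maximum and SBP/DBP off characteristic
ratios, score the residuum for artifacts, and hand an ensemble-averaged,
MAP/DBP-calibrated pulse to a pluggable central-BP estimator.

The default central estimator is a deliberately simple surrogate (a single
damping factor applied to the calibrated pulse height above MAP). It stands
in for proprietary device transformations, which are not public; the
package's claim is the validation pipeline around the estimator, not the
estimator itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps

from .types import BrachialEstimate, CentralEstimate, PressureWaveform

DEFAULT_SYSTOLIC_RATIO = 0.55
DEFAULT_DIASTOLIC_RATIO = 0.70
MIN_PULSE_AMPLITUDE = 0.1  # mmHg, floor below which pulses are discarded
RESIDUUM_WINDOW_S = 2.0
RESIDUUM_THRESHOLD = 1.5  # mmHg RMS per window
RESIDUUM_RECORDING_FRACTION = 0.30


@dataclass
class Pulse:
    """One oscillometric pulse: half-open interval with its envelope point."""

    foot: int
    end: int
    amplitude: float
    cuff_pressure: float


@dataclass
class OscillometricRecording:
    """Decomposition of a cuff recording; raw = ramp + pulsatile on the
    deflation segment."""

    raw: PressureWaveform
    segment: slice
    ramp: np.ndarray
    pulsatile: np.ndarray
    deflation_rate: float
    foot_points: np.ndarray = None
    pulses: list = None
    envelope: np.ndarray = None  # columns (cuff pressure, smoothed amplitude)


def separate_pulsatile(raw: PressureWaveform, *, min_span: float = 60.0):
    """Split the deflation segment into a robust linear ramp and pulses.

    The deflation segment is the longest run where the heavily smoothed
    pressure falls; it must span at least ``min_span`` mmHg. The ramp is a
    Huber-robust straight line whose intercept is then re-centred so the
    pulsatile residual has exactly zero mean. Returns an
    ``OscillometricRecording`` (without pulses yet).
    """
    if raw.channel != "cuff":
        raise ValueError("separate_pulsatile expects a cuff channel")
    fs = raw.sampling_rate
    x = raw.samples
    win = max(3, int(round(2.0 * fs)) | 1)
    trend = sps.savgol_filter(x, win, 1)
    falling = np.gradient(trend) * fs < -1.0
    if not falling.any():
        raise ValueError("no monotone deflation segment found")
    # close brief interruptions (artifacts) shorter than one second
    gap = np.flatnonzero(~falling)
    if gap.size:
        runs = np.split(gap, np.flatnonzero(np.diff(gap) > 1) + 1)
        for g in runs:
            inside = g[0] > 0 and g[-1] < falling.size - 1
            if inside and g.size < fs:
                falling[g] = True
    idx = np.flatnonzero(falling)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)
    seg = slice(int(run[0]), int(run[-1]) + 1)
    if x[seg].max() - x[seg].min() < min_span:
        raise ValueError("deflation segment spans less than "
                         f"{min_span:g} mmHg")

    t = np.arange(seg.start, seg.stop) / fs
    rlm = sm.RLM(x[seg], sm.add_constant(t), M=sm.robust.norms.HuberT())
    fit = rlm.fit()
    intercept, slope = fit.params
    ramp = intercept + slope * t
    # re-centre so the pulsatile component is zero-mean over the segment
    offset = float((x[seg] - ramp).mean())
    ramp = ramp + offset
    pulsatile = x[seg] - ramp
    return OscillometricRecording(
        raw=raw, segment=seg, ramp=ramp, pulsatile=pulsatile,
        deflation_rate=float(-slope))


def find_pulses(rec: OscillometricRecording, *,
                min_amplitude: float = MIN_PULSE_AMPLITUDE):
    """Detect per-cycle foot points and envelope points on the pulsatile
    component. Amplitudes are peak-to-trough of the band-limited pulsatile
    signal within each foot-to-foot interval; the cuff pressure attached to
    a pulse is the ramp value at its foot. Fills ``rec`` in place and
    returns ``(foot_points, pulses)``; foot indices are relative to the raw
    signal."""
    fs = rec.raw.sampling_rate
    y = rec.pulsatile
    nyq = fs / 2.0
    sos = sps.butter(4, min(12.0, 0.8 * nyq) / nyq, output="sos")
    xf = sps.sosfiltfilt(sos, y)

    # dominant cardiac period from the autocorrelation in 30-180 /min
    ac = sps.correlate(xf - xf.mean(), xf - xf.mean(), mode="full")
    ac = ac[ac.size // 2:]
    lo, hi = int(fs * 60.0 / 180.0), min(int(fs * 60.0 / 30.0), ac.size - 1)
    if hi <= lo:
        raise ValueError("recording too short to estimate pulse rate")
    period = (lo + int(np.argmax(ac[lo:hi]))) / fs

    peaks, _ = sps.find_peaks(xf, distance=max(1, int(0.6 * period * fs)),
                              prominence=min_amplitude)
    if peaks.size < 2:
        raise ValueError("too few pulses for envelope")
    feet = []
    first_lo = max(0, peaks[0] - int(period * fs))
    feet.append(first_lo + int(np.argmin(xf[first_lo:peaks[0]])))
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        feet.append(p0 + int(np.argmin(xf[p0:p1])))
    feet = np.asarray(feet, dtype=int)

    # Pulse amplitude (peak-to-trough) estimated from the per-cycle RMS of
    # the band-limited pulsatile signal: the RMS pools the whole cycle, so
    # its noise sits near the matched-filter bound, unlike a max-minus-min
    # which rides on two noisy extremes. A per-recording scale maps RMS to
    # peak-to-peak units and the small-pulse noise floor is subtracted.
    sos_amp = sps.butter(4, min(6.0, 0.8 * nyq) / nyq, output="sos")
    xa = sps.sosfiltfilt(sos_amp, y)
    rms = np.array([
        float(np.sqrt(np.mean((xa[f0:f1] - xa[f0:f1].mean()) ** 2)))
        for f0, f1 in zip(feet[:-1], feet[1:])])
    floor = np.percentile(rms, 5)
    rms = np.sqrt(np.maximum(rms ** 2 - floor ** 2, 0.0))
    ptp = np.array([float(np.ptp(xf[f0:f1]))
                    for f0, f1 in zip(feet[:-1], feet[1:])])
    strong = rms >= 0.5 * rms.max()
    scale = float(np.median(ptp[strong] / rms[strong])) if strong.any() else 3.0
    amps = scale * rms

    pulses = []
    for f0, f1, amp in zip(feet[:-1], feet[1:], amps):
        if amp < min_amplitude:
            continue
        # cuff pressure at the foot instant: ramp plus the (near-zero)
        # band-limited pulsatile value there, i.e. the actual cuff level
        pulses.append(Pulse(foot=int(f0) + rec.segment.start,
                            end=int(f1) + rec.segment.start,
                            amplitude=float(amp),
                            cuff_pressure=float(rec.ramp[f0] + xf[f0])))
    if len(pulses) < 5:
        raise ValueError("too few pulses for envelope")
    rec.foot_points = feet + rec.segment.start
    rec.pulses = pulses
    return rec.foot_points, pulses


def _smooth_envelope(pulses: list, smooth_n: int = 5) -> np.ndarray:
    """(cuff pressure, amplitude) pairs sorted by cuff pressure, amplitudes
    moving-averaged over ``smooth_n`` consecutive pulses in time order."""
    amps = np.array([p.amplitude for p in pulses], float)
    cuffs = np.array([p.cuff_pressure for p in pulses], float)
    if smooth_n > 1:
        pad = smooth_n // 2
        padded = np.concatenate([np.repeat(amps[0], pad), amps,
                                 np.repeat(amps[-1], pad)])
        amps = np.convolve(padded, np.ones(smooth_n) / smooth_n, mode="valid")
    order = np.argsort(cuffs)
    return np.column_stack([cuffs[order], amps[order]])


def envelope_bp(pulses: list, *, systolic_ratio: float = DEFAULT_SYSTOLIC_RATIO,
                diastolic_ratio: float = DEFAULT_DIASTOLIC_RATIO,
                smooth_n: int = 5):
    """Brachial SBP/MAP/DBP from the oscillometric envelope.

    MAP is the cuff pressure at the smoothed envelope maximum (refined by a
    quadratic fit to the points within 30% of the peak); SBP is the cuff
    pressure above MAP where the envelope falls to ``systolic_ratio`` of its
    maximum, DBP the cuff pressure below MAP at ``diastolic_ratio``, both
    linearly interpolated. Returns ``(estimate, envelope)``.
    """
    if len(pulses) < 5:
        raise ValueError("need at least 5 pulses for an envelope")
    env = _smooth_envelope(pulses, smooth_n)
    c, a = env[:, 0], env[:, 1]
    imax = int(np.argmax(a))
    if imax in (0, len(a) - 1):
        raise ValueError("cuff range did not bracket MAP "
                         "(envelope has no interior maximum)")
    # refine the peak location: the envelope top is near-parabolic on a log
    # scale, so fit a concave quadratic to log-amplitude over the upper half
    top = a >= 0.5 * a[imax]
    map_ = float(c[imax])
    amax = float(a[imax])
    if top.sum() >= 5:
        coef = np.polyfit(c[top], np.log(a[top]), 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if c[top].min() <= vertex <= c[top].max():
                map_ = float(vertex)
                amax = float(np.exp(np.polyval(coef, vertex)))

    def _crossing(target: float, side: str) -> float:
        if side == "high":
            cs, as_ = c[imax:], a[imax:]
        else:
            cs, as_ = c[:imax + 1][::-1], a[:imax + 1][::-1]
        below = np.flatnonzero(as_ <= target)
        if below.size == 0:
            raise ValueError(
                f"envelope tail does not reach the {side}-side ratio")
        j = below[0]
        if j == 0:
            return float(cs[0])
        c0, c1 = cs[j - 1], cs[j]
        a0, a1 = as_[j - 1], as_[j]
        return float(c0 + (target - a0) * (c1 - c0) / (a1 - a0))

    sbp = _crossing(systolic_ratio * amax, "high")
    dbp = _crossing(diastolic_ratio * amax, "low")
    est = BrachialEstimate(sbp=sbp, map=map_, dbp=dbp,
                           systolic_ratio=systolic_ratio,
                           diastolic_ratio=diastolic_ratio)
    return est, env


def _pulse_template(rec: OscillometricRecording, n_points: int = 100):
    """Amplitude-normalised mean pulse over all detected pulses."""
    fs = rec.raw.sampling_rate
    nyq = fs / 2.0
    sos = sps.butter(4, min(12.0, 0.8 * nyq) / nyq, output="sos")
    xf = sps.sosfiltfilt(sos, rec.pulsatile)
    grid = np.linspace(0.0, 1.0, n_points)
    shapes = []
    for p in rec.pulses:
        seg = xf[p.foot - rec.segment.start:p.end - rec.segment.start]
        if seg.size < 4 or seg.max() - seg.min() <= 0:
            continue
        u = np.linspace(0.0, 1.0, seg.size)
        norm = (seg - seg.min()) / (seg.max() - seg.min())
        shapes.append(np.interp(grid, u, norm))
    if not shapes:
        raise ValueError("no usable pulses for a template")
    return np.mean(shapes, axis=0)


def residuum_score(rec: OscillometricRecording, *,
                   window_s: float = RESIDUUM_WINDOW_S,
                   threshold: float = RESIDUUM_THRESHOLD,
                   recording_fraction: float = RESIDUUM_RECORDING_FRACTION):
    """Artifact scoring from the spread between actual and expected cuff
    pressure.

    The expected signal is ramp + per-pulse reconstruction (the normalised
    template scaled to each pulse's amplitude and level); the residuum is
    everything left over. Windows of ``window_s`` whose residuum RMS exceeds
    ``threshold`` are flagged; the recording is flagged when more than
    ``recording_fraction`` of windows are.
    Returns ``(scores, window_flags, recording_flag)``.
    """
    if rec.pulses is None:
        raise ValueError("run find_pulses first")
    template = _pulse_template(rec)
    recon = np.zeros_like(rec.pulsatile)
    fs = rec.raw.sampling_rate
    nyq = fs / 2.0
    sos = sps.butter(4, min(12.0, 0.8 * nyq) / nyq, output="sos")
    xf = sps.sosfiltfilt(sos, rec.pulsatile)
    for p in rec.pulses:
        i0, i1 = p.foot - rec.segment.start, p.end - rec.segment.start
        seg = xf[i0:i1]
        u = np.linspace(0.0, 1.0, seg.size)
        recon[i0:i1] = seg.min() + (seg.max() - seg.min()) * np.interp(
            u, np.linspace(0.0, 1.0, template.size), template)
    residuum = rec.pulsatile - recon

    wlen = max(1, int(round(window_s * fs)))
    n_win = residuum.size // wlen
    if n_win == 0:
        n_win, wlen = 1, residuum.size
    scores = np.array([
        float(np.sqrt(np.mean(residuum[i * wlen:(i + 1) * wlen] ** 2)))
        for i in range(n_win)])
    flags = scores > threshold
    recording_flag = bool(flags.mean() > recording_fraction)
    return scores, flags, recording_flag


def ensemble_pulse(rec: OscillometricRecording, map_value: float, *,
                   half_width: float = 15.0, n_points: int = 100) -> np.ndarray:
    """Amplitude-normalised mean of the pulses recorded while the cuff was
    within ``half_width`` mmHg of the envelope MAP."""
    fs = rec.raw.sampling_rate
    nyq = fs / 2.0
    sos = sps.butter(4, min(12.0, 0.8 * nyq) / nyq, output="sos")
    xf = sps.sosfiltfilt(sos, rec.pulsatile)
    grid = np.linspace(0.0, 1.0, n_points)
    shapes = []
    for p in rec.pulses:
        if abs(p.cuff_pressure - map_value) > half_width:
            continue
        seg = xf[p.foot - rec.segment.start:p.end - rec.segment.start]
        if seg.size < 4 or seg.max() - seg.min() <= 0:
            continue
        u = np.linspace(0.0, 1.0, seg.size)
        shapes.append(np.interp(grid, u,
                                (seg - seg.min()) / (seg.max() - seg.min())))
    if not shapes:
        raise ValueError("no pulses near the envelope maximum")
    return np.mean(shapes, axis=0)


# ---------------------------------------------------------------------------
# pluggable central estimators

ESTIMATORS: dict = {}


def register_estimator(name: str):
    """Decorator registering ``fn(ensemble, brachial, **params)`` under
    ``name``; the function must return a CentralEstimate."""
    def _wrap(fn):
        ESTIMATORS[name] = fn
        return fn
    return _wrap


def calibrate_pulse(ensemble: np.ndarray, map_value: float,
                    dbp_value: float) -> np.ndarray:
    """Affine-map the unit ensemble pulse so its minimum equals DBP and its
    time-average equals MAP (the MAP/DBP calibration preprocessing step)."""
    g = np.asarray(ensemble, float)
    gmin, gmean = g.min(), g.mean()
    if gmean <= gmin:
        raise ValueError("degenerate ensemble pulse")
    return dbp_value + (map_value - dbp_value) * (g - gmin) / (gmean - gmin)


@register_estimator("surrogate")
def _surrogate_estimator(ensemble: np.ndarray, brachial: BrachialEstimate,
                         *, alpha: float = 0.8) -> CentralEstimate:
    """Transparent surrogate: cDBP and cMAP pass through the calibrated
    values; cSBP damps the calibrated pulse height above MAP by ``alpha``
    (peripheral-to-central pulse-pressure de-amplification)."""
    cal = calibrate_pulse(ensemble, brachial.map, brachial.dbp)
    csbp = brachial.map + alpha * (float(cal.max()) - brachial.map)
    return CentralEstimate(csbp=csbp, cmap=brachial.map, cdbp=brachial.dbp,
                           estimator_id=f"surrogate(alpha={alpha:g})",
                           calibration_map=brachial.map,
                           calibration_dbp=brachial.dbp)


def estimate_central(rec: OscillometricRecording, brachial: BrachialEstimate,
                     *, estimator: str = "surrogate",
                     **params) -> CentralEstimate:
    """Run a registered central estimator on the calibrated ensemble pulse."""
    if estimator not in ESTIMATORS:
        raise KeyError(f"estimator {estimator!r} not registered; "
                       f"known: {sorted(ESTIMATORS)}")
    ens = ensemble_pulse(rec, brachial.map)
    result = ESTIMATORS[estimator](ens, brachial, **params)
    if not (result.cdbp <= result.cmap <= result.csbp):
        raise ValueError("estimator returned unordered central pressures")
    return result


def process_cuff(raw: PressureWaveform, *,
                 systolic_ratio: float = DEFAULT_SYSTOLIC_RATIO,
                 diastolic_ratio: float = DEFAULT_DIASTOLIC_RATIO,
                 estimator: str = "surrogate", **estimator_params):
    """Full oscillometric chain on one cuff recording.

    Returns ``(rec, brachial, central, artifact_flag)``.
    """
    rec = separate_pulsatile(raw)
    find_pulses(rec)
    brachial, env = envelope_bp(rec.pulses, systolic_ratio=systolic_ratio,
                                diastolic_ratio=diastolic_ratio)
    rec.envelope = env
    _, _, artifact_flag = residuum_score(rec)
    central = estimate_central(rec, brachial, estimator=estimator,
                               **estimator_params)
    return rec, brachial, central, artifact_flag
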