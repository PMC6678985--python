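"""Per-beat analysis of invasive aortic pressure recordings.

Turns a raw catheter waveform into foot-delimited beats, per-beat
SBP/DBP/MAP, an automated outlier clearing, a recording summary, and the
inclusion/exclusion verdict used for hemodynamic stability (beat-to-beat SD
limits of 10/6/6 mmHg for SBP/MAP/DBP) and severe arrhythmia (more than 30%
of beats cleared).

Per-beat values follow the catheter-lab convention: SBP is the peak of the
pulse wave, DBP the lowest point, MAP the area under the curve normalised by
beat duration (time-average).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import Beat, PressureWaveform, RecordingSummary

#: hemodynamic-stability SD limits in mmHg, order (SBP, MAP, DBP)
DEFAULT_SD_LIMITS = (10.0, 6.0, 6.0)
#: a recording is severe arrhythmia when more than this fraction is cleared
DEFAULT_ARRHYTHMIA_LIMIT = 0.30
#: floor on the robust SD so identical-beat recordings do not flag everything
MAD_FLOOR_MMHG = 1.0
#: minimum plausible systolic upstroke slope, mmHg/s
MIN_UPSTROKE_SLOPE = 25.0


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float = 15.0) -> np.ndarray:
    """Zero-phase low-pass used only for localisation, never for values."""
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x.astype(float)
    sos = sps.butter(4, cutoff_hz / nyq, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_beats(waveform: PressureWaveform, *, slope_frac: float = 0.4,
                 refractory_s: float = 0.25,
                 smooth_hz: float = 15.0) -> np.ndarray:
    """Locate beat feet (diastolic minima before each systolic upstroke).

    Upstroke events are samples where the smoothed derivative exceeds
    ``slope_frac`` of the recording's peak positive slope, separated by a
    refractory period; each foot is the minimum of the smoothed signal in the
    window since the previous event. Returns strictly increasing foot
    indices; beats are the half-open intervals between consecutive feet, so
    partial first/last beats are dropped implicitly.
    """
    if waveform.channel != "invasive":
        raise ValueError("detect_beats expects an invasive channel")
    if waveform.duration < 2.0:
        raise ValueError("recording must be at least 2 s long")
    fs = waveform.sampling_rate
    x = _smooth(waveform.samples, fs, smooth_hz)
    if float(x.max() - x.min()) < 10.0:
        raise ValueError("no beats: pulse amplitude below physiologic floor")
    dx = np.gradient(x) * fs
    peak_slope = float(dx.max(initial=0.0))
    threshold = max(slope_frac * peak_slope, MIN_UPSTROKE_SLOPE)

    above = dx >= threshold
    if not above.any():
        raise ValueError("no beats: no systolic upstroke found")
    # group threshold crossings into events, refractory-limited
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    groups = np.split(idx, breaks + 1)
    refractory = int(round(refractory_s * fs))
    events = []
    for g in groups:
        e = int(g[np.argmax(dx[g])])
        if events and e - events[-1] < refractory:
            if dx[e] > dx[events[-1]]:
                events[-1] = e
            continue
        events.append(e)
    if len(events) < 2:
        raise ValueError("no beats: fewer than 2 upstrokes detected")

    gaps = np.diff(events)
    median_gap = int(np.median(gaps))
    feet = []
    for j, e in enumerate(events):
        lo = events[j - 1] if j > 0 else max(0, e - median_gap)
        if lo >= e:
            continue
        feet.append(lo + int(np.argmin(x[lo:e])))
    feet = np.unique(np.asarray(feet, dtype=int))
    if feet.size < 2:
        raise ValueError("no beats: fewer than 2 feet detected")

    rate = 60.0 * fs / np.median(np.diff(feet))
    if not (30.0 <= rate <= 180.0):
        warnings.warn(f"non-physiologic dominant rate {rate:.0f}/min",
                      stacklevel=2)
    return feet


def beat_values(waveform: PressureWaveform, start: int, end: int):
    """(SBP, DBP, MAP) of the half-open beat [start, end).

    MAP is the trapezoidal integral over the beat divided by its duration;
    the sample at ``end`` (the next foot) closes the integral when present.
    """
    n = waveform.samples.size
    if not (0 <= start < end <= n):
        raise ValueError("beat bounds outside waveform")
    seg = waveform.samples[start:end]
    stop = min(end + 1, n)
    integ_seg = waveform.samples[start:stop]
    sbp = float(seg.max())
    dbp = float(seg.min())
    map_ = float(np.trapezoid(integ_seg) / (integ_seg.size - 1))
    # guard against degenerate one-interval rounding
    map_ = min(max(map_, dbp), sbp)
    return sbp, dbp, map_


def analyze_beats(waveform: PressureWaveform, feet: np.ndarray) -> list:
    """Build Beat objects for every complete foot-to-foot interval."""
    beats = []
    for s, e in zip(feet[:-1], feet[1:]):
        sbp, dbp, map_ = beat_values(waveform, int(s), int(e))
        beats.append(Beat(start=int(s), end=int(e), sbp=sbp, dbp=dbp, map=map_))
    return beats


def clear_outlier_beats(beats: list,
                        policy: tuple = (("sbp", "dbp", "duration"), 3.0),
                        *, mad_floor: float = MAD_FLOOR_MMHG) -> list:
    """Flag beats deviating from the per-recording median as outliers.

    A beat is excluded when any policy metric (per-beat SBP or DBP in mmHg,
    or beat duration — the metric that catches extrasystoles with attenuated
    pulses and compensatory pauses) deviates from the recording median by
    more than ``k`` robust-SD units (robust SD = 1.4826 * MAD). The robust
    SD is floored — at ``mad_floor`` mmHg for pressures, and at 4% of the
    median for durations (tolerating foot-localisation jitter on flat
    diastolic tails) — so near-identical beats flag nothing.
    Statistics are computed over all beats, so re-running is a no-op.
    Returns a new list with updated flags.
    """
    metrics, k = policy
    if isinstance(metrics, str):
        metrics = (metrics,)
    if len(beats) < 3:
        raise ValueError("need at least 3 beats for outlier clearing")
    flagged = np.zeros(len(beats), dtype=bool)
    for m in metrics:
        vals = np.array([getattr(b, m) for b in beats], float)
        med = np.median(vals)
        floor = 0.04 * abs(med) if m == "duration" else mad_floor
        robust_sd = max(1.4826 * np.median(np.abs(vals - med)), floor)
        flagged |= np.abs(vals - med) > k * robust_sd
    if flagged.all():
        raise ValueError("recording unusable: all beats excluded")
    out = []
    for b, f in zip(beats, flagged):
        out.append(Beat(start=b.start, end=b.end, sbp=b.sbp, dbp=b.dbp,
                        map=b.map, kept=not f,
                        exclusion_reason="outlier" if f else "none"))
    return out


def summarize_recording(beats: list, *, sd_limits=DEFAULT_SD_LIMITS,
                        arrhythmia_limit=DEFAULT_ARRHYTHMIA_LIMIT
                        ) -> RecordingSummary:
    """Means and sample SDs (n-1) over kept beats; exclusion bookkeeping.

    A single kept beat yields SDs of 0 by convention.
    """
    kept = [b for b in beats if b.kept]
    if not kept:
        raise ValueError("no kept beats to summarise")

    def _stats(vals):
        v = np.asarray(vals, float)
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    mean_sbp, sd_sbp = _stats([b.sbp for b in kept])
    mean_dbp, sd_dbp = _stats([b.dbp for b in kept])
    mean_map, sd_map = _stats([b.map for b in kept])
    n_total = len(beats)
    n_excl = n_total - len(kept)
    stability_pass = not (sd_sbp > sd_limits[0] or sd_map > sd_limits[1]
                          or sd_dbp > sd_limits[2])
    arrhythmia_flag = n_excl / n_total > arrhythmia_limit
    return RecordingSummary(
        mean_sbp=mean_sbp, mean_dbp=mean_dbp, mean_map=mean_map,
        sd_sbp=sd_sbp, sd_dbp=sd_dbp, sd_map=sd_map,
        n_beats_total=n_total, n_beats_excluded=n_excl,
        stability_pass=stability_pass, arrhythmia_flag=arrhythmia_flag)


def apply_exclusion_rules(summary: RecordingSummary, *,
                          sd_limits=DEFAULT_SD_LIMITS,
                          arrhythmia_limit=DEFAULT_ARRHYTHMIA_LIMIT):
    """Recording verdict: include / exclude_arrhythmia / exclude_stability.

    Arrhythmia (cleared fraction strictly above the limit) is checked first;
    stability uses strict inequalities against the (SBP, MAP, DBP) SD limits,
    attributed to the first limit exceeded in that order.
    """
    if summary.excluded_fraction > arrhythmia_limit:
        return ("exclude_arrhythmia",
                f"{100 * summary.excluded_fraction:.1f}% of beats cleared")
    for name, sd, limit in (("sbp", summary.sd_sbp, sd_limits[0]),
                            ("map", summary.sd_map, sd_limits[1]),
                            ("dbp", summary.sd_dbp, sd_limits[2])):
        if sd > limit:
            return ("exclude_stability",
                    f"sd_{name} {sd:.2f} mmHg > {limit:g} mmHg")
    return ("include", "")


def analyze_recording(waveform: PressureWaveform, *,
                      outlier_policy=(("sbp", "dbp", "duration"), 3.0),
                      sd_limits=DEFAULT_SD_LIMITS,
                      arrhythmia_limit=DEFAULT_ARRHYTHMIA_LIMIT):
    """Full invasive chain: detect -> values -> clear -> summarise -> verdict.

    Returns ``(beats, summary, verdict, detail)``.
    """
    feet = detect_beats(waveform)
    beats = analyze_beats(waveform, feet)
    beats = clear_outlier_beats(beats, outlier_policy)
    summary = summarize_recording(beats, sd_limits=sd_limits,
                                  arrhythmia_limit=arrhythmia_limit)
    verdict, detail = apply_exclusion_rules(
        summary, sd_limits=sd_limits, arrhythmia_limit=arrhythmia_limit)
    return beats, summary, verdict, detail
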