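"""Catheter frequency-response QC from fast-flush tests.

A fluid-filled catheter-transducer line behaves as an underdamped
second-order system. After the sudden release of a flush (a rectangular
pressure pulse of at least 180 mmHg) the line rings down around the
baseline. The oscillation frequency is read off as the reciprocal of the
time between the 2nd and 3rd oscillation (one full cycle), and the damping
coefficient from the amplitude ratio of those two oscillations via the
logarithmic decrement:

    delta = ln(A2 / A3),   zeta = delta / sqrt(4 pi^2 + delta^2)

Strictly, 1/(t3 - t2) measures the damped frequency fd; the undamped
natural frequency is fn = fd / sqrt(1 - zeta^2). The uncorrected value is
reported by default (it is the conventional bedside rule); pass
``correct_damping=True`` to apply the correction.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .types import FlushTestResult, PressureWaveform

#: acceptance ranges (inclusive) observed across routinely checked systems
DEFAULT_FN_RANGE = (15.0, 29.0)
DEFAULT_ZETA_RANGE = (0.14, 0.29)


def detect_oscillations(waveform: PressureWaveform, *,
                        min_amplitude: float = 0.5):
    """Times and amplitudes of successive extrema after the flush release.

    The release is the largest negative step of the signal; the settled
    baseline is the mean of the final 20%. Amplitudes are measured as
    ``|extremum - baseline|``. Returns ``(times, amplitudes, values)`` with
    ``values`` the signed deviations, all in time order. Raises when fewer
    than 3 extrema are found.
    """
    if waveform.channel != "flush":
        raise ValueError("detect_oscillations expects a flush channel")
    x = waveform.samples
    fs = waveform.sampling_rate
    release = int(np.argmin(np.diff(x)))
    baseline = float(x[-max(2, x.size // 5):].mean())
    post = x[release:] - baseline
    floor = max(min_amplitude, 1e-3 * float(np.abs(post).max()))

    maxima, _ = sps.find_peaks(post, prominence=floor)
    minima, _ = sps.find_peaks(-post, prominence=floor)
    idx = np.sort(np.concatenate([maxima, minima]))
    idx = idx[np.abs(post[idx]) >= floor]
    if idx.size < 3:
        raise ValueError("no oscillations: fewer than 3 extrema after release")
    # sub-sample refinement: a parabola through the three samples around
    # each extremum (one sample of quantisation is ~1 Hz at 20 Hz ringing)
    times = np.empty(idx.size)
    values = np.empty(idx.size)
    for j, i in enumerate(idx):
        if 0 < i < post.size - 1:
            y0, y1, y2 = post[i - 1], post[i], post[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            times[j] = (release + i + delta) / fs + waveform.t0
            values[j] = y1 - 0.25 * (y0 - y2) * delta
        else:
            times[j] = (release + i) / fs + waveform.t0
            values[j] = post[i]
    return times, np.abs(values), values


def natural_frequency(t2: float, t3: float) -> float:
    """Oscillation frequency from the times of two consecutive same-sign
    oscillations (one full cycle): fn = 1 / (t3 - t2)."""
    if t3 <= t2:
        raise ValueError("oscillation times must be strictly increasing")
    return 1.0 / (t3 - t2)


def damping_coefficient(a2: float, a3: float) -> float:
    """Damping ratio from the amplitude ratio of two consecutive
    oscillations via the logarithmic decrement."""
    if not (a2 > a3 > 0):
        raise ValueError("require A2 > A3 > 0 (damped oscillation)")
    delta = math.log(a2 / a3)
    return delta / math.sqrt(4.0 * math.pi ** 2 + delta ** 2)


def qc_check(result: FlushTestResult, *, fn_range=DEFAULT_FN_RANGE,
             zeta_range=DEFAULT_ZETA_RANGE):
    """Inclusive range check of fn and zeta; returns (pass, report line)."""
    fn_ok = fn_range[0] <= result.natural_frequency <= fn_range[1]
    z_ok = zeta_range[0] <= result.damping_coefficient <= zeta_range[1]
    ok = fn_ok and z_ok
    line = (f"fn={result.natural_frequency:.1f} Hz "
            f"[{fn_range[0]:g}-{fn_range[1]:g}] "
            f"{'ok' if fn_ok else 'FAIL'}; "
            f"zeta={result.damping_coefficient:.2f} "
            f"[{zeta_range[0]:g}-{zeta_range[1]:g}] "
            f"{'ok' if z_ok else 'FAIL'}")
    return ok, line


def analyze_flush(waveform: PressureWaveform, *,
                  correct_damping: bool = False,
                  fn_range=DEFAULT_FN_RANGE,
                  zeta_range=DEFAULT_ZETA_RANGE) -> FlushTestResult:
    """Full flush-test analysis: extrema -> fn and zeta -> QC verdict.

    Oscillations are the same-sign extrema after release (alternating
    extrema are half-cycles); the 2nd and 3rd of these are one full cycle
    apart, as the bedside rule requires.
    """
    times, amps, values = detect_oscillations(waveform)
    # same-sign series: every other extremum, matching the sign of the first
    osc_t = times[0::2]
    osc_a = amps[0::2]
    if osc_t.size < 3:
        raise ValueError("no oscillations: fewer than 3 same-sign extrema")
    fn = natural_frequency(float(osc_t[1]), float(osc_t[2]))
    zeta = damping_coefficient(float(osc_a[1]), float(osc_a[2]))
    if correct_damping:
        fn = fn / math.sqrt(1.0 - zeta ** 2)
    result = FlushTestResult(
        natural_frequency=fn, damping_coefficient=zeta,
        oscillation_times=list(osc_t), oscillation_amplitudes=list(osc_a))
    result.qc_pass, _ = qc_check(result, fn_range=fn_range,
                                 zeta_range=zeta_range)
    return result
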