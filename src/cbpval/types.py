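"""Shared domain containers for the central-BP validation pipeline.

Pressures are in mmHg throughout, times in seconds, rates in Hz unless a
field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("invasive", "cuff", "flush")


@dataclass
class PressureWaveform:
    """Uniformly sampled pressure signal.

    Parameters
    ----------
    samples
        Pressure samples in mmHg. Must be finite, length >= 2.
    sampling_rate
        Samples per second, > 0.
    channel
        One of ``invasive``, ``cuff``, ``flush``.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: str = "invasive"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("waveform needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class Beat:
    """One cardiac cycle as a half-open sample interval [start, end)."""

    start: int
    end: int
    sbp: float
    dbp: float
    map: float
    kept: bool = True
    exclusion_reason: str = "none"  # none | outlier | artifact

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("beat end must exceed start")
        if not (self.dbp <= self.map <= self.sbp):
            raise ValueError("beat must satisfy dbp <= map <= sbp")

    @property
    def duration(self) -> int:
        """Beat length in samples."""
        return self.end - self.start


@dataclass
class RecordingSummary:
    """Per-recording averages over kept beats plus inclusion bookkeeping."""

    mean_sbp: float
    mean_dbp: float
    mean_map: float
    sd_sbp: float
    sd_dbp: float
    sd_map: float
    n_beats_total: int
    n_beats_excluded: int
    stability_pass: bool
    arrhythmia_flag: bool

    @property
    def excluded_fraction(self) -> float:
        return self.n_beats_excluded / self.n_beats_total


@dataclass
class FlushTestResult:
    """Second-order characteristics of a fluid-filled catheter system."""

    natural_frequency: float
    damping_coefficient: float
    oscillation_times: list = field(default_factory=list)
    oscillation_amplitudes: list = field(default_factory=list)
    qc_pass: bool = False

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if not (0.0 < self.damping_coefficient < 1.0):
            raise ValueError("damping_coefficient must lie in (0, 1)")


@dataclass
class BrachialEstimate:
    """Brachial SBP/MAP/DBP derived from the oscillometric envelope."""

    sbp: float
    map: float
    dbp: float
    method: str = "envelope_ratio"
    systolic_ratio: float = 0.55
    diastolic_ratio: float = 0.70

    def __post_init__(self) -> None:
        if not (self.dbp < self.map < self.sbp):
            raise ValueError("brachial estimate must satisfy dbp < map < sbp")


@dataclass
class CentralEstimate:
    """Central SBP/MAP/DBP produced by a registered estimator."""

    csbp: float
    cmap: float
    cdbp: float
    estimator_id: str
    calibration_map: float
    calibration_dbp: float

    def __post_init__(self) -> None:
        if not (self.cdbp <= self.cmap <= self.csbp):
            raise ValueError("central estimate must satisfy cdbp <= cmap <= csbp")


@dataclass
class PairedMeasurement:
    """One patient's invasive reference vs device-estimated central BP."""

    patient_id: str
    invasive: tuple  # (csbp, cmap, cdbp)
    estimated: tuple  # (csbp, cmap, cdbp)
    site: str = ""
    included: bool = True
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.included:
            vals = np.array(list(self.invasive) + list(self.estimated), float)
            if not (np.all(np.isfinite(vals)) and np.all(vals > 0)):
                raise ValueError("included pairs need positive, finite pressures")


@dataclass
class AgreementResult:
    """Bland-Altman and correlation statistics for one pressure component."""

    component: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    r: float
    r_squared: float
    slope: float
    intercept: float
    ba_slope: float
    ba_intercept: float
    bin_counts: tuple  # counts with |error| < 5 / 10 / 15 mmHg (cumulative)
    bin_pct: tuple  # unrounded percentages
    bin_pct_rounded: tuple  # one decimal, for reporting
    r_defined: bool = True


@dataclass
class GradingResult:
    """Pass/fail verdicts for one component across validation protocols."""

    component: str
    artery_pass: bool
    aami2013_pass: bool
    iso2018_prob: float
    iso2018_pass: bool
    bhs_grade: str
    bhs_grade_rounded: str
    bhs_rounding_disagrees: bool
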