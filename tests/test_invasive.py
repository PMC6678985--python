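"""Invasive beat analysis: detection, per-beat values, clearing, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbpval.invasive import (analyze_beats, apply_exclusion_rules,
                             beat_values, clear_outlier_beats, detect_beats,
                             summarize_recording)
from cbpval.synthcohort import BeatShapeParams, synth_aortic_waveform
from cbpval.types import Beat, PressureWaveform, RecordingSummary


def _waveform(samples, fs=240.0):
    return PressureWaveform(np.asarray(samples, float), fs, channel="invasive")


def _beats(sbp_values, dbp=80.0, map_=None, duration=100):
    out = []
    for i, s in enumerate(sbp_values):
        m = map_ if map_ is not None else (s + dbp) / 2.0
        out.append(Beat(start=i * duration, end=(i + 1) * duration,
                        sbp=float(s), dbp=dbp, map=float(m)))
    return out


class TestBeatValues:
    def test_square_beat_analytic(self):
        # half at 120, half at 80, midpoint sample at 100: MAP exactly 100
        samples = np.concatenate([np.full(50, 120.0), [100.0],
                                  np.full(51, 80.0)])
        wf = _waveform(samples)
        sbp, dbp, map_ = beat_values(wf, 0, 100)
        assert (sbp, dbp) == (120.0, 80.0)
        assert map_ == pytest.approx(100.0, abs=1e-9)

    def test_constant_beat(self):
        wf = _waveform(np.full(600, 100.0))
        assert beat_values(wf, 0, 240) == (100.0, 100.0, 100.0)

    def test_bounds_outside_signal_raise(self):
        wf = _waveform(np.full(100, 90.0))
        with pytest.raises(ValueError, match="bounds"):
            beat_values(wf, 50, 101)

    def test_synthetic_beat_map_matches_target(self):
        shape = BeatShapeParams(sbp=145.1, dbp=72.1, map_target=101.5,
                                heart_rate=69, rng_seed=0, noise_sd=0.0,
                                sbp_sd=0.0, dbp_sd=0.0, map_frac_sd=0.0,
                                hr_jitter_frac=0.0)
        wf, truth = synth_aortic_waveform(shape, 20.0, 500.0)
        feet = detect_beats(wf)
        for b in analyze_beats(wf, feet):
            assert b.map == pytest.approx(101.5, abs=1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_order_invariant_on_random_beats(self, seed):
        rng = np.random.default_rng(seed)
        wf = _waveform(60.0 + 80.0 * rng.random(400))
        sbp, dbp, map_ = beat_values(wf, 0, 399)
        assert dbp <= map_ <= sbp


class TestDetectBeats:
    def test_beat_count_60bpm_20s(self):
        shape = BeatShapeParams(sbp=120, dbp=80, map_target=100,
                                heart_rate=60, rng_seed=5)
        wf, truth = synth_aortic_waveform(shape, 20.0, 240.0)
        feet = detect_beats(wf)
        assert len(feet) - 1 in (19, 20)

    def test_feet_within_20ms_of_ground_truth(self):
        shape = BeatShapeParams(sbp=145.1, dbp=72.1, map_target=101.5,
                                heart_rate=69, rng_seed=1, noise_sd=0.0)
        wf, truth = synth_aortic_waveform(shape, 90.0, 240.0)
        feet = detect_beats(wf) / wf.sampling_rate
        m = min(len(feet), len(truth))
        err = np.abs(feet[:m] - truth["t_foot"].to_numpy()[:m])
        assert err.max() <= 0.020

    def test_constant_signal_has_no_beats(self):
        with pytest.raises(ValueError, match="no beats"):
            detect_beats(_waveform(np.full(2000, 100.0)))

    def test_wrong_channel_rejected(self):
        wf = PressureWaveform(np.zeros(500) + 50, 240.0, channel="cuff")
        with pytest.raises(ValueError, match="invasive"):
            detect_beats(wf)


class TestClearOutliers:
    def test_two_dropped_pulses_cleared(self):
        sbp = np.full(102, 140.0)
        sbp[[30, 31]] = 100.0  # two artifact waves 40 mmHg low
        beats = clear_outlier_beats(_beats(sbp))
        excluded = [i for i, b in enumerate(beats) if not b.kept]
        assert excluded == [30, 31]

    def test_identical_beats_keep_everything(self):
        beats = clear_outlier_beats(_beats(np.full(20, 120.0)))
        assert all(b.kept for b in beats)

    def test_single_small_deviation_tolerated(self):
        # {120 x 9, 121}: MAD = 0, floored robust SD keeps the 121 beat
        beats = clear_outlier_beats(_beats([120.0] * 9 + [121.0]))
        assert all(b.kept for b in beats)

    def test_idempotent(self):
        sbp = np.concatenate([np.full(50, 130.0), [90.0, 170.0]])
        once = clear_outlier_beats(_beats(sbp))
        twice = clear_outlier_beats(once)
        assert [b.kept for b in once] == [b.kept for b in twice]

    def test_duration_metric_flags_short_cycles(self):
        beats = _beats(np.full(30, 120.0))
        beats[10] = Beat(start=beats[10].start, end=beats[10].start + 60,
                         sbp=120.0, dbp=80.0, map=100.0)
        flagged = clear_outlier_beats(beats)
        assert not flagged[10].kept
        assert sum(not b.kept for b in flagged) == 1

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="3 beats"):
            clear_outlier_beats(_beats([120.0, 121.0]))


class TestSummary:
    def test_hand_computed_mean_and_sd(self):
        s = summarize_recording(_beats([140.0, 150.0]))
        assert s.mean_sbp == pytest.approx(145.0)
        assert s.sd_sbp == pytest.approx(7.0711, abs=1e-3)

    def test_single_beat_sd_zero(self):
        s = summarize_recording(_beats([140.0]))
        assert s.sd_sbp == 0.0 and s.sd_dbp == 0.0 and s.sd_map == 0.0

    def test_statistics_over_kept_beats_only(self):
        beats = _beats([140.0, 150.0])
        beats.append(Beat(start=200, end=300, sbp=40.0, dbp=30.0, map=35.0,
                          kept=False, exclusion_reason="outlier"))
        s = summarize_recording(beats)
        assert s.mean_sbp == pytest.approx(145.0)
        assert s.n_beats_excluded == 1
        assert s.excluded_fraction == pytest.approx(1 / 3)

    def test_no_kept_beats_raises(self):
        beats = _beats([120.0, 121.0])
        for b in beats:
            b.kept = False
        with pytest.raises(ValueError, match="kept"):
            summarize_recording(beats)


def _summary(sd_sbp=2.0, sd_map=2.0, sd_dbp=2.0, excluded=0, total=100):
    return RecordingSummary(mean_sbp=140, mean_dbp=80, mean_map=100,
                            sd_sbp=sd_sbp, sd_dbp=sd_dbp, sd_map=sd_map,
                            n_beats_total=total, n_beats_excluded=excluded,
                            stability_pass=True, arrhythmia_flag=False)


class TestExclusionRules:
    def test_sbp_sd_above_10_excluded(self):
        verdict, detail = apply_exclusion_rules(_summary(sd_sbp=10.1))
        assert verdict == "exclude_stability" and "sd_sbp" in detail

    def test_boundaries_are_strict(self):
        # study-level mean SDs with exactly 30% cleared: still included
        v, _ = apply_exclusion_rules(
            _summary(sd_sbp=4.08, sd_map=2.83, sd_dbp=2.31, excluded=30))
        assert v == "include"
        v, _ = apply_exclusion_rules(_summary(sd_sbp=10.0, sd_map=6.0,
                                              sd_dbp=6.0))
        assert v == "include"

    def test_arrhythmia_above_30_percent(self):
        v, _ = apply_exclusion_rules(_summary(excluded=31))
        assert v == "exclude_arrhythmia"

    def test_arrhythmia_checked_before_stability(self):
        v, _ = apply_exclusion_rules(_summary(sd_sbp=15.0, excluded=40))
        assert v == "exclude_arrhythmia"

    def test_stability_attribution_order_sbp_map_dbp(self):
        _, detail = apply_exclusion_rules(
            _summary(sd_sbp=11.0, sd_map=7.0, sd_dbp=7.0))
        assert "sd_sbp" in detail
        _, detail = apply_exclusion_rules(_summary(sd_map=7.0, sd_dbp=7.0))
        assert "sd_map" in detail


def test_map_robust_to_resampling_across_site_rates():
    """Per-beat MAP agrees within 0.5 mmHg between 2000 and 240 Hz."""
    shape = BeatShapeParams(sbp=145.1, dbp=72.1, map_target=101.5,
                            heart_rate=69, rng_seed=8, noise_sd=0.0)
    maps = {}
    for fs in (2000.0, 240.0):
        wf, truth = synth_aortic_waveform(shape, 30.0, fs)
        beats = analyze_beats(wf, detect_beats(wf))
        maps[fs] = np.array([b.map for b in beats])
    n = min(len(maps[2000.0]), len(maps[240.0]))
    assert np.abs(maps[2000.0][:n] - maps[240.0][:n]).max() < 0.5
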