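"""Oscillometric chain: ramp separation, pulses, envelope, residuum,
central estimation."""

import numpy as np
import pytest

from cbpval.oscillo import (ESTIMATORS, Pulse, calibrate_pulse, envelope_bp,
                            estimate_central, find_pulses, process_cuff,
                            register_estimator, residuum_score,
                            separate_pulsatile)
from cbpval.synthcohort import synth_cuff_recording
from cbpval.types import BrachialEstimate, PressureWaveform


@pytest.fixture(scope="module")
def recording():
    wf, truth = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=3)
    rec = separate_pulsatile(wf)
    find_pulses(rec)
    return wf, truth, rec


class TestSeparatePulsatile:
    def test_deflation_rate_recovered(self, recording):
        _, _, rec = recording
        assert rec.deflation_rate == pytest.approx(4.0, abs=0.1)

    def test_raw_equals_ramp_plus_pulsatile(self, recording):
        wf, _, rec = recording
        recon = rec.ramp + rec.pulsatile
        assert np.abs(wf.samples[rec.segment] - recon).max() < 1e-9

    def test_pulsatile_is_zero_mean(self, recording):
        _, _, rec = recording
        assert abs(rec.pulsatile.mean()) < 0.2

    def test_pulse_free_ramp_has_no_pulsatile(self):
        t = np.arange(0, 30.0, 1 / 100.0)
        raw = PressureWaveform(180.0 - 4.0 * t, 100.0, channel="cuff")
        rec = separate_pulsatile(raw)
        assert np.abs(rec.pulsatile).max() < 1e-6

    def test_no_deflation_raises(self):
        raw = PressureWaveform(np.full(3000, 120.0), 100.0, channel="cuff")
        with pytest.raises(ValueError, match="deflation"):
            separate_pulsatile(raw)


class TestFindPulses:
    def test_pulse_count_tracks_heart_rate(self, recording):
        wf, _, rec = recording
        expected = 69.0 / 60.0 * wf.duration
        assert len(rec.pulses) == pytest.approx(expected, abs=3)

    def test_feet_within_30ms_of_ground_truth(self):
        wf, truth, = None, None
        wf, truth = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=3,
                                         noise_sd=0.0)
        rec = separate_pulsatile(wf)
        find_pulses(rec)
        tt = truth["foot_times"]
        for p in rec.pulses:
            f = p.foot / wf.sampling_rate
            assert np.abs(tt - f).min() <= 0.030

    def test_too_few_pulses_raises(self):
        t = np.arange(0, 20.0, 1 / 100.0)
        raw = PressureWaveform(160.0 - 4.0 * t
                               + 0.01 * np.sin(2 * np.pi * 1.2 * t),
                               100.0, channel="cuff")
        rec = separate_pulsatile(raw)
        with pytest.raises(ValueError, match="too few pulses"):
            find_pulses(rec)


def _triangle_pulses(peak=100.0, width=50.0, spacing=5.0, amp=3.0):
    cuffs = np.arange(peak + width, peak - width - 1, -spacing)
    pulses = []
    for i, c in enumerate(cuffs):
        a = amp * max(0.0, 1.0 - abs(c - peak) / width)
        pulses.append(Pulse(foot=i * 100, end=(i + 1) * 100,
                            amplitude=a, cuff_pressure=float(c)))
    return pulses


class TestEnvelopeBP:
    def test_map_roundtrip(self, recording):
        _, _, rec = recording
        est, env = envelope_bp(rec.pulses)
        assert est.map == pytest.approx(107.0, abs=2.0)

    def test_symmetric_triangle_gives_symmetric_ratios(self):
        est, _ = envelope_bp(_triangle_pulses(), systolic_ratio=0.5,
                             diastolic_ratio=0.5, smooth_n=5)
        assert est.map == pytest.approx(100.0, abs=1.0)
        assert (est.sbp - est.map) == pytest.approx(est.map - est.dbp,
                                                    abs=0.5)

    def test_monotone_envelope_rejected(self):
        pulses = [Pulse(foot=i * 100, end=(i + 1) * 100,
                        amplitude=0.2 + 0.1 * i, cuff_pressure=180.0 - 4 * i)
                  for i in range(20)]
        with pytest.raises(ValueError, match="bracket MAP"):
            envelope_bp(pulses)

    def test_needs_five_pulses(self):
        with pytest.raises(ValueError, match="5 pulses"):
            envelope_bp(_triangle_pulses()[:4])


class TestResiduum:
    def test_clean_recording_not_flagged(self, recording):
        _, _, rec = recording
        scores, flags, rec_flag = residuum_score(rec)
        assert not rec_flag
        assert flags.sum() == 0

    def test_step_artifact_flags_containing_window(self):
        wf, _ = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=3)
        samples = wf.samples.copy()
        step_t = 15.0
        samples[int(step_t * wf.sampling_rate):] += 5.0
        rec = separate_pulsatile(
            PressureWaveform(samples, wf.sampling_rate, channel="cuff"))
        find_pulses(rec)
        scores, flags, rec_flag = residuum_score(rec)
        wlen = 2.0
        w_step = int((step_t - rec.segment.start / wf.sampling_rate) / wlen)
        assert flags[max(0, w_step - 1):w_step + 2].any()
        assert not rec_flag

    def test_widespread_corruption_flags_recording(self):
        wf, _ = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=3)
        fs = wf.sampling_rate
        samples = wf.samples.copy()
        n_win = int(wf.duration / 2.0)
        t = np.arange(samples.size) / fs
        burst = 3.0 * np.sign(np.sin(2 * np.pi * 13.0 * t))
        for w in range(0, n_win, 2):  # corrupt every other window (50%)
            sl = slice(int(w * 2 * fs), int((w * 2 + 2) * fs))
            samples[sl] += burst[sl]
        rec = separate_pulsatile(
            PressureWaveform(samples, fs, channel="cuff"))
        find_pulses(rec)
        _, flags, rec_flag = residuum_score(rec)
        assert rec_flag
        assert flags.mean() > 0.3


class TestCentralEstimation:
    def test_calibration_contract(self):
        g = np.concatenate([np.linspace(0, 1, 40), np.linspace(1, 0, 60)])
        cal = calibrate_pulse(g, 107.0, 85.0)
        assert cal.mean() == pytest.approx(107.0, abs=1e-9)
        assert cal.min() == pytest.approx(85.0, abs=1e-9)

    def test_surrogate_formula_arithmetic(self):
        # ensemble whose calibrated maximum is exactly 150 for MAP/DBP
        # 107/85: mean fraction 22/65 makes max scale to 65 above DBP
        g = np.concatenate([np.ones(22), np.zeros(43)])
        brachial = BrachialEstimate(sbp=150, map=107, dbp=85)
        est = ESTIMATORS["surrogate"](g, brachial, alpha=0.8)
        assert est.csbp == pytest.approx(107 + 0.8 * (150 - 107), abs=1e-9)
        assert est.csbp == pytest.approx(141.4, abs=1e-6)
        ident = ESTIMATORS["surrogate"](g, brachial, alpha=1.0)
        assert ident.csbp == pytest.approx(150.0, abs=1e-9)
        assert (est.cmap, est.cdbp) == (107, 85)

    def test_full_chain_produces_ordered_estimate(self, recording):
        wf, _, _ = recording
        rec, brachial, central, artifact = process_cuff(wf)
        assert central.cdbp <= central.cmap <= central.csbp
        assert central.estimator_id.startswith("surrogate")
        assert not artifact

    def test_pressure_offset_equivariance(self):
        """Adding a constant to the cuff start pressure shifts the estimate
        by that constant and nothing else."""
        wf, _ = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=6)
        shifted = PressureWaveform(wf.samples + 10.0, wf.sampling_rate,
                                   channel="cuff")
        _, b1, c1, _ = process_cuff(wf)
        _, b2, c2, _ = process_cuff(shifted)
        assert b2.map - b1.map == pytest.approx(10.0, abs=0.5)
        assert c2.csbp - c1.csbp == pytest.approx(10.0, abs=0.8)

    def test_time_origin_irrelevant(self):
        wf, _ = synth_cuff_recording((150, 107, 85), 69.0, rng_seed=6)
        moved = PressureWaveform(wf.samples, wf.sampling_rate,
                                 channel="cuff", t0=42.0)
        _, _, c1, _ = process_cuff(wf)
        _, _, c2, _ = process_cuff(moved)
        assert c1.csbp == pytest.approx(c2.csbp, abs=1e-9)

    def test_unknown_estimator_rejected(self, recording):
        _, _, rec = recording
        brachial = BrachialEstimate(sbp=150, map=107, dbp=85)
        with pytest.raises(KeyError):
            estimate_central(rec, brachial, estimator="antares")

    def test_estimator_registry_contract(self, recording):
        _, _, rec = recording

        @register_estimator("identity_test")
        def _ident(ensemble, brachial, **kw):
            return ESTIMATORS["surrogate"](ensemble, brachial, alpha=1.0)

        brachial = BrachialEstimate(sbp=150, map=107, dbp=85)
        est = estimate_central(rec, brachial, estimator="identity_test")
        assert est.cmap == 107
        ESTIMATORS.pop("identity_test")
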