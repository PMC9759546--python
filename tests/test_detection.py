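"""Detector unit and property tests: filtering, framing, band power,
baseline statistics, acute/chronic triggering, blanking and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from snfsim import detection as det
from snfsim.records import IctalParams, LFPRecord, SeizureEvent, SeizureGroundTruth
from snfsim.spectral import BANDS, band_power
from snfsim.synthetic import assemble_recording, generate_baseline, inject_artifacts

FS = 500.0


def _record(x, fs=FS):
    return LFPRecord(np.atleast_2d(x), fs=fs,
                     channel_labels=tuple(f"ch{i}"
                                          for i in range(np.atleast_2d(x).shape[0])))


class TestHighpass:
    def test_constant_becomes_zero(self):
        rec = _record(np.full(5000, 3.0))
        out = det.highpass(rec, 0.5, zero_phase=True)
        assert np.abs(out.samples[0, 500:]).max() < 0.05

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 20, 1 / FS)
        rec = _record(np.sin(2 * np.pi * 10 * t))
        out = det.highpass(rec, 0.5, zero_phase=True)
        mid = out.samples[0, 2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        # evaluate the designed filter's response at 0.05 Hz directly
        sos = signal.butter(2, 0.5, btype="highpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=[0.05], fs=FS)
        assert np.abs(h[0]) < 0.1

    def test_cutoff_at_nyquist_rejected(self):
        rec = _record(np.zeros(1000))
        with pytest.raises(ValueError, match="Nyquist"):
            det.highpass(rec, FS / 2)


class TestFrameStream:
    @pytest.mark.parametrize("n,expected_frames", [(1000, 7), (250, 1),
                                                   (249, 0), (374, 1),
                                                   (375, 2)])
    def test_frame_counts(self, n, expected_frames):
        frames, times = det.frame_stream(np.zeros((2, n)), 250, 0.5, FS)
        assert frames.shape[0] == expected_frames
        assert len(times) == expected_frames

    def test_frame_start_spacing(self):
        _, times = det.frame_stream(np.zeros((1, 1000)), 250, 0.5, FS)
        np.testing.assert_allclose(np.diff(times), 125 / FS)
        assert times[0] == 0.0


class TestBandPower:
    def test_zero_frame_zero_power(self):
        assert band_power(np.zeros(250), BANDS["alpha"], FS) == 0.0

    def test_sinusoid_power_in_band(self):
        t = np.arange(250) / FS
        frame = np.sin(2 * np.pi * 10 * t)
        in_band = band_power(frame, BANDS["alpha"], FS)
        total = band_power(frame, (0.5, 249.0), FS)
        assert in_band / total >= 0.9

    def test_bands_sum_below_total(self):
        rng = np.random.default_rng(0)
        frame = rng.standard_normal(250)
        total = frame.var()
        parts = sum(band_power(frame, BANDS[b], FS) for b in BANDS)
        assert parts < total

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            band_power(np.zeros(250), (13.0, 13.0), FS)


class TestBaselineStats:
    def test_threshold_stable_across_halves(self, baseline_600,
                                            detector_config):
        first = det.compute_baseline(baseline_600, detector_config,
                                     window=300.0)
        second_rec = LFPRecord(baseline_600.samples[:, 150_000:],
                               fs=baseline_600.fs,
                               channel_labels=baseline_600.channel_labels)
        second = det.compute_baseline(second_rec, detector_config,
                                      window=300.0)
        ratio = first.band_power / second.band_power
        assert np.all(np.abs(ratio - 1) < 0.25)

    def test_short_record_rejected(self, detector_config):
        rec = generate_baseline(10.0, seed=1)
        with pytest.raises(ValueError, match="shorter"):
            det.compute_baseline(rec, detector_config, window=300.0)

    def test_all_zero_record_warns_degenerate(self, detector_config):
        rec = _record(np.zeros((2, int(300 * FS))))
        with pytest.warns(UserWarning, match="degenerate"):
            stats = det.compute_baseline(rec, detector_config)
        assert np.all(stats.band_power == 0)

    def test_median_robust_to_single_artifact(self, detector_config):
        rec = generate_baseline(300.0, seed=5)
        clean = det.compute_baseline(rec, detector_config)
        dirty_rec = rec.copy()
        i0 = int(100 * FS)
        dirty_rec.samples[:, i0:i0 + 250] += 2.0  # one huge 0.5 s transient
        dirty = det.compute_baseline(dirty_rec, detector_config)
        np.testing.assert_allclose(dirty.band_power, clean.band_power,
                                   rtol=0.05)


class TestAcute:
    def test_missing_baseline_rejected(self, event_record, detector_config):
        with pytest.raises(ValueError, match="baseline"):
            det.detect_acute(event_record[0], detector_config, None)

    def test_trigger_latency_on_constructed_event(self, event_record,
                                                  detector_config):
        rec, truth = event_record
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_acute(rec, detector_config, baseline)
        first = min(t for t in res.triggers if t >= 600.0)
        assert 600.0 <= first <= 601.5

    def test_blanking_delays_trigger(self, event_record, detector_config):
        rec, _ = event_record
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_acute(rec, detector_config, baseline,
                               blanking_windows=[(600.0, 605.0)])
        assert all(not (600.0 <= t < 605.0) for t in res.triggers)
        assert min(t for t in res.triggers if t >= 600.0) >= 605.0

    def test_threshold_monotonicity(self, event_record):
        rec, _ = event_record
        counts = []
        for factor in (1.5, 2.0, 3.0, 5.0):
            cfg = det.DetectorConfig(threshold_factor=factor)
            baseline = det.compute_baseline(rec, cfg)
            counts.append(len(det.detect_acute(rec, cfg, baseline).triggers))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_causality_no_trigger_before_onset(self, event_record,
                                               detector_config):
        rec, truth = event_record
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_acute(rec, detector_config, baseline)
        onset = truth.events[0].onset
        assert all(t >= onset for t in res.triggers)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(b0=st.floats(0.0, 800.0), blen=st.floats(1.0, 60.0))
    def test_blanking_property_no_triggers_inside(self, b0, blen,
                                                  event_record,
                                                  detector_config,
                                                  baseline_stats):
        rec, _ = event_record
        res = det.detect_acute(rec, detector_config, baseline_stats,
                               blanking_windows=[(b0, b0 + blen)])
        assert all(not (b0 <= t < b0 + blen) for t in res.triggers)


class TestSpikeFeatures:
    def test_zero_signal_undefined(self):
        f = det.spike_features(np.zeros(int(4 * FS)), FS)
        assert (f.amplitude, f.rate) == (0.0, 0.0)
        assert f.undefined

    def test_regular_pulse_train(self):
        x = np.zeros(int(10 * FS))
        x[::100] = 1.0  # exact 5 Hz
        f = det.spike_features(x, FS, mad=0.01)
        assert f.rate == pytest.approx(5.0, abs=0.1)
        assert f.regularity == pytest.approx(0.0, abs=1e-6)

    def test_poisson_train_cv_matches_dead_time_oracle(self):
        # exponential ISIs give CV ~ 1; the 50 ms peak-separation dead time
        # leaves survivors with ISI ~ d + Exp(m), hence CV = m / (d + m)
        rng = np.random.default_rng(42)
        mean_isi = 0.5
        isi = rng.exponential(mean_isi, size=300)
        times = np.cumsum(isi)
        n = int(times[-1] * FS) + 10
        x = np.zeros(n)
        x[(times * FS).astype(int)] = 1.0
        f = det.spike_features(x, FS, mad=0.01)
        expected = mean_isi / (0.05 + mean_isi)
        assert f.regularity == pytest.approx(expected, rel=0.15)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            det.spike_features(np.zeros(100), FS)


class TestChronic:
    @pytest.fixture(scope="class")
    def artifact_hour(self):
        rec = generate_baseline(3600.0, seed=21)
        return inject_artifacts(rec, 12.0, seed=7)

    def test_acute_false_positives_on_artifacts(self, artifact_hour,
                                                detector_config):
        rec, _ = artifact_hour
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_acute(rec, detector_config, baseline)
        assert len(res.triggers) >= 1

    def test_chronic_rejects_artifacts(self, artifact_hour, detector_config,
                                       spike_config):
        rec, _ = artifact_hour
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_chronic(rec, detector_config, spike_config,
                                 baseline=baseline)
        assert res.triggers == []

    def test_chronic_single_trigger_near_onset(self, detector_config,
                                               spike_config):
        rec, truth = assemble_recording(
            [SeizureEvent(1800.0, 1830.0, "bilateral")], seed=31,
            duration_s=3600.0,
            ictal_params=IctalParams(band_gain=(3.0, 3.0, 3.0)))
        rec, truth = inject_artifacts(rec, 12.0, seed=8, truth=truth)
        baseline = det.compute_baseline(rec, detector_config)
        res = det.detect_chronic(rec, detector_config, spike_config,
                                 baseline=baseline)
        assert len(res.triggers) == 1
        assert abs(res.triggers[0] - 1800.0) <= 3.0


class TestScoring:
    def _truth(self, events):
        return SeizureGroundTruth(events=[SeizureEvent(*e) for e in events])

    def _result(self, triggers):
        return det.DetectionResult(triggers=list(triggers), events=[],
                                   frame_times=np.array([]),
                                   feature_trace=np.array([]))

    def test_perfect_detector(self):
        truth = self._truth([(10 * i, 10 * i + 5) for i in range(1, 11)])
        res = self._result([10 * i + 1 for i in range(1, 11)])
        score = det.score_detection(res, truth, 3600.0)
        assert score.sensitivity == 1.0
        assert score.fp_per_hour == 0.0

    def test_no_triggers_zero_sensitivity(self):
        truth = self._truth([(10.0, 20.0)])
        score = det.score_detection(self._result([]), truth, 3600.0)
        assert score.sensitivity == 0.0
        assert score.median_latency is None

    def test_single_early_trigger_is_one_fp_per_hour(self):
        truth = self._truth([(100.0, 120.0)])
        score = det.score_detection(self._result([50.0]), truth, 3600.0)
        assert score.fp_per_hour == pytest.approx(1.0)

    def test_latency_is_first_trigger_minus_onset(self):
        truth = self._truth([(100.0, 120.0)])
        score = det.score_detection(self._result([101.5, 103.0]), truth,
                                    3600.0)
        assert score.median_latency == pytest.approx(1.5)
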