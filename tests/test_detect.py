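import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from fuzzyspike.detect import (
    DetectionConfig,
    bandpass_filter,
    compute_threshold,
    detect_peaks,
    estimate_noise_sigma,
    extract_waveforms,
)
from fuzzyspike.io import RawRecording, SpikeEvent
from fuzzyspike.simulate import SimConfig, generate_recording, make_templates


class TestNoiseAndThreshold:
    def test_sigma_from_alternating_trace(self):
        x = np.tile([0.6745, -0.6745], 500)
        assert estimate_noise_sigma(x) == pytest.approx(1.0)
        assert compute_threshold(estimate_noise_sigma(x)) == pytest.approx(4.0)

    def test_sigma_of_zero_trace_is_zero(self):
        assert estimate_noise_sigma(np.zeros(100)) == 0.0

    def test_sigma_of_standard_gaussian_is_one(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        assert estimate_noise_sigma(x) == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("sigma,mult,expected", [(1.0, 4.0, 4.0), (0.0, 4.0, 0.0), (0.25, 4.0, 1.0)])
    def test_threshold_is_multiplier_times_sigma(self, sigma, mult, expected):
        assert compute_threshold(sigma, mult) == expected

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(-1.0)


class TestBandpass:
    def test_dc_removed(self):
        rec = RawRecording(np.full(20_000, 3.0), fs=20_000.0)
        out = bandpass_filter(rec, (300.0, 5000.0))
        assert np.max(np.abs(out.samples)) < 1e-6 * 3.0

    def test_passband_tone_preserved(self):
        fs = 20_000.0
        t = np.arange(int(fs)) / fs
        rec = RawRecording(np.sin(2 * np.pi * 1000.0 * t), fs=fs)
        out = bandpass_filter(rec, (300.0, 5000.0))
        mid = out.samples[2000:-2000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        rec = RawRecording(np.zeros(1000), fs=10_000.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, (300.0, 6000.0))


def _parabola_trace(height, t0_samples, fs=10_000.0, n=400, half_width=6.0):
    """A single parabolic bump with analytic vertex at t0 (in samples)."""
    i = np.arange(n)
    y = height * (1.0 - ((i - t0_samples) / half_width) ** 2)
    return RawRecording(np.maximum(y, 0.0), fs=fs)


class TestDetectPeaks:
    def test_vertex_recovered_to_subsample_accuracy(self):
        rec = _parabola_trace(5.0, 200.37)
        events = detect_peaks(rec, threshold=4.0)
        assert len(events) == 1
        assert abs(events[0].time_s * rec.fs - 200.37) < 0.05
        assert events[0].amplitude == pytest.approx(5.0, abs=1e-6)

    def test_subthreshold_bump_ignored(self):
        rec = _parabola_trace(3.0, 200.0)
        assert detect_peaks(rec, threshold=4.0) == []

    def test_refractory_keeps_first_of_close_pair(self):
        fs = 10_000.0
        a = _parabola_trace(5.0, 100.0, fs=fs, n=300).samples
        b = _parabola_trace(5.0, 105.0, fs=fs, n=300).samples  # 0.5 ms later
        rec = RawRecording(np.maximum(a, b), fs=fs)
        events = detect_peaks(rec, threshold=4.0, cfg=DetectionConfig(dead_time_ms=1.0))
        assert len(events) == 1
        assert abs(events[0].time_s * fs - 100.0) < 0.1

    def test_event_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(rng.standard_normal(50_000), fs=10_000.0)
        counts = [len(detect_peaks(rec, thr)) for thr in (1.0, 1.5, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestExtraction:
    def test_window_geometry_at_10khz(self):
        """Raw cut 1.8 ms, x2 spline to 36 samples, truncated to 24 = 1.2 ms."""
        fs = 10_000.0
        cfg = DetectionConfig(filter_signal=False)
        pre = int(round(cfg.pre_ms * 1e-3 * fs))
        post = int(round(cfg.post_ms * 1e-3 * fs))
        assert (pre + post) / fs == pytest.approx(1.8e-3)
        rec = _parabola_trace(5.0, 200.0, fs=fs)
        wm = extract_waveforms(rec, detect_peaks(rec, 4.0), cfg)
        assert wm.A.shape == (1, 24)
        assert wm.dt == 1.0 / (2 * fs)
        assert wm.span_s == pytest.approx(1.2e-3)
        assert wm.peak_col == 10

    def test_noiseless_spike_matches_spline_resampled_template(self):
        fs = 10_000.0
        templates = make_templates(fs)
        tpl = templates.templates[1]
        off = templates.peak_offset(1)
        x = np.zeros(4000)
        n0 = 2000
        x[n0 - off : n0 - off + len(tpl)] = tpl
        rec = RawRecording(x, fs=fs)
        wm = extract_waveforms(rec, [SpikeEvent(n0 / fs, 1.0)], DetectionConfig())
        # independent resampling of the same raw window, aligned at the
        # spline's continuous maximum (the template peak falls between
        # samples, so the aligned window is centred off the integer grid)
        grid = np.arange(n0 - 10, n0 + 13)
        spl = CubicSpline(grid, x[n0 - 10 : n0 + 13])
        fine = n0 + np.linspace(-2, 2, 129)
        q = fine[np.argmax(spl(fine))]
        expected = spl(q + 0.5 * (np.arange(36) - 16))[6:30]
        assert np.max(np.abs(wm.A[0] - expected)) < 1e-6

    def test_edge_event_dropped_and_counted(self):
        rec = RawRecording(np.zeros(100), fs=10_000.0)
        wm = extract_waveforms(rec, [SpikeEvent(3 / 10_000.0, 1.0)], DetectionConfig())
        assert wm.n == 0 and wm.n_dropped == 1

    def test_zero_noise_recovery_within_one_sample(self):
        """Detector recovers every isolated, non-edge truth spike exactly;
        spikes inside another spike's refractory dead time are suppressed
        by design and excluded."""
        cfg = SimConfig(duration=20.0, noise_level=0.0, firing_rate=5.0, seed=3)
        rec, truth = generate_recording(cfg)
        sigma = estimate_noise_sigma(rec.samples)
        events = detect_peaks(rec, compute_threshold(sigma), DetectionConfig(filter_signal=False))
        det_t = np.array([e.time_s for e in events])
        times = np.array([e.time_s for e in truth])
        checked = 0
        for i, e in enumerate(truth):
            isolated = np.min(np.abs(np.delete(times, i) - e.time_s)) > 1.1e-3
            if isolated and 0.002 < e.time_s < rec.duration - 0.002:
                assert np.min(np.abs(det_t - e.time_s)) <= 1.0 / cfg.fs + 1e-9
                checked += 1
        assert checked > 200

    def test_alignment_concentrates_peak_column(self, sorted_easy):
        """Spline re-alignment pins the waveform maximum near the peak column."""
        wm = sorted_easy.waveforms
        argmax = wm.A.argmax(axis=1)
        # isolated spikes align exactly; windows containing a second spike may not
        assert np.mean(np.abs(argmax - wm.peak_col) <= 1) > 0.9
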