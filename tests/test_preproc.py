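"""Spike preprocessing: artifact removal, filtering, detection, SNR."""

import numpy as np
import pytest
from scipy import signal

from acprecess.preproc import (
    ContinuousRecording,
    DetectionConfig,
    WaveformCluster,
    bandpass,
    compute_snr,
    detect_spikes,
    estimate_noise_sigma,
    remove_artifact_spectral,
)
from acprecess.synth import biphasic_template, gen_extracellular_trace

FS = 30000.0


def band_power(x, fs, f0, half=0.5):
    f, p = signal.periodogram(x, fs)
    sel = (f >= f0 - half) & (f <= f0 + half)
    return p[sel].mean()


class TestArtifactRemoval:
    def test_sinusoid_power_suppressed_to_neighbor_level(self, rng):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + rng.normal(0, 0.01, t.size)
        rec = ContinuousRecording(x, FS)
        clean = remove_artifact_spectral(rec, [10.0], halfwidth=0.5)
        inside = band_power(clean.samples, FS, 10.0, 0.5)
        neighbor = band_power(clean.samples, FS, 12.0, 0.5)
        # within 3 dB of the flanking level
        assert inside < neighbor * 2.0
        assert clean.n_samples == rec.n_samples

    def test_empty_target_list_is_identity(self, rng):
        rec = ContinuousRecording(rng.normal(size=1000), FS)
        out = remove_artifact_spectral(rec, [])
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_two_target_bands_both_suppressed(self, rng):
        t = np.arange(int(10 * FS)) / FS
        x = (np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t)
             + rng.normal(0, 0.01, t.size))
        clean = remove_artifact_spectral(ContinuousRecording(x, FS), [10.0, 20.0])
        for f0 in (10.0, 20.0):
            assert band_power(clean.samples, FS, f0) < \
                band_power(clean.samples, FS, f0 + 2.0) * 2.0

    def test_band_beyond_nyquist_raises(self, rng):
        rec = ContinuousRecording(rng.normal(size=100), 100.0)
        with pytest.raises(ValueError):
            remove_artifact_spectral(rec, [60.0])


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(int(1 * FS)) / FS
        x = np.sin(2 * np.pi * 1000 * t)
        out = bandpass(ContinuousRecording(x, FS))
        mid = slice(int(0.2 * FS), int(0.8 * FS))
        assert np.abs(out.samples[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_tone_rejected(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(ContinuousRecording(x, FS))
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        # > 40 dB attenuation
        assert np.abs(out.samples[mid]).max() < 1e-2

    def test_dc_trace_goes_to_zero(self):
        out = bandpass(ContinuousRecording(np.full(3000, 5.0), FS))
        assert np.abs(out.samples[1000:2000]).max() < 1e-6

    def test_invalid_band_raises(self):
        cfg = DetectionConfig(band_low=300.0, band_high=3000.0)
        with pytest.raises(ValueError):
            bandpass(ContinuousRecording(np.zeros(100), 5000.0), cfg)


class TestNoiseSigma:
    def test_recovers_gaussian_sigma(self, rng):
        x = rng.normal(0, 2.0, size=1_000_000)
        assert estimate_noise_sigma(ContinuousRecording(x, FS)) == pytest.approx(
            2.0, abs=0.01)

    def test_constant_magnitude_trace(self):
        x = np.tile([3.0, -3.0], 500)
        assert estimate_noise_sigma(ContinuousRecording(x, FS)) == pytest.approx(
            3.0 / 0.6745)

    def test_all_zero_trace(self):
        assert estimate_noise_sigma(ContinuousRecording(np.zeros(100), FS)) == 0.0

    def test_robust_to_outliers_unlike_std(self, rng):
        x = rng.normal(0, 1.0, size=100_000)
        sigma0 = estimate_noise_sigma(ContinuousRecording(x, FS))
        contaminated = x.copy()
        idx = rng.choice(x.size, size=x.size // 100, replace=False)
        contaminated[idx] = 100.0
        sigma1 = estimate_noise_sigma(ContinuousRecording(contaminated, FS))
        assert abs(sigma1 - sigma0) / sigma0 < 0.05
        assert contaminated.std() > 10 * x.std()


def rice_bound(duration_s, lam, f_low=300.0, f_high=3000.0):
    """Expected |x| > lam*sigma exceedance events of band-limited Gaussian
    noise (Rice crossing rate for an ideal flat band, both polarities)."""
    nu0 = np.sqrt((f_high ** 3 - f_low ** 3) / (3 * (f_high - f_low)))
    return 2.0 * duration_s * nu0 * np.exp(-lam ** 2 / 2.0)


class TestDetection:
    def test_injected_templates_all_recovered_after_bandpass(self):
        rec, truth = gen_extracellular_trace(n_spikes=40, noise_sigma=1.0,
                                             duration=10.0, seed=5)
        cfg = DetectionConfig()
        cluster = detect_spikes(bandpass(rec, cfg), cfg)
        true_times = np.asarray(truth["true_spike_times_s"])
        tol = 2.0 / rec.sampling_rate
        hits = sum(np.min(np.abs(cluster.spike_times - t)) <= tol
                   for t in true_times)
        assert hits == 40
        # extra (noise) detections stay within the crossing-rate bound
        assert cluster.n_spikes - 40 <= 2 * rice_bound(10.0, 4.0) + 5

    def test_high_threshold_detects_exactly_the_injections(self):
        rec, truth = gen_extracellular_trace(n_spikes=40, noise_sigma=1.0,
                                             duration=10.0, seed=5)
        cfg = DetectionConfig(lambda_factor=5.0)
        cluster = detect_spikes(bandpass(rec, cfg), cfg)
        assert cluster.n_spikes == 40

    def test_noise_only_count_below_exceedance_bound(self, rng):
        n = int(30 * FS)
        rec = ContinuousRecording(rng.normal(0, 1.0, size=n), FS)
        cfg = DetectionConfig()
        cluster = detect_spikes(bandpass(rec, cfg), cfg)
        assert cluster.n_spikes <= 2 * rice_bound(30.0, 4.0) + 5

    def test_default_threshold_is_four_sigma(self):
        assert DetectionConfig().lambda_factor == 4.0

    def test_snippet_geometry_and_alignment(self):
        rec, _ = gen_extracellular_trace(n_spikes=10, duration=5.0, seed=2)
        cluster = detect_spikes(rec, DetectionConfig(), sigma=1.0)
        assert cluster.waveforms.shape[1] == 32
        # extremum sits at the alignment index
        peaks = np.abs(cluster.waveforms).argmax(axis=1)
        assert np.all(peaks == cluster.pre_samples)

    def test_recall_and_precision_at_six_sigma(self):
        tpl = biphasic_template(amplitude=6.0)
        rec, truth = gen_extracellular_trace(template=tpl, n_spikes=350,
                                             noise_sigma=1.0, duration=10.0,
                                             min_gap_s=0.002, seed=9)
        cfg = DetectionConfig()
        cluster = detect_spikes(bandpass(rec, cfg), cfg)
        true_times = np.asarray(truth["true_spike_times_s"])
        tol = 2.0 / rec.sampling_rate
        hits = sum(np.min(np.abs(cluster.spike_times - t)) <= tol for t in true_times)
        assert hits / len(true_times) >= 0.95          # recall
        good = sum(np.min(np.abs(true_times - t)) <= tol for t in cluster.spike_times)
        assert good / cluster.n_spikes >= 0.95         # precision


class TestArtifactPipeline:
    def test_detection_after_artifact_removal_matches_clean(self):
        tpl = biphasic_template(amplitude=8.0)
        clean, truth = gen_extracellular_trace(template=tpl, n_spikes=40,
                                               noise_sigma=1.0, duration=10.0, seed=3)
        t = np.arange(clean.n_samples) / clean.sampling_rate
        dirty = ContinuousRecording(
            clean.samples + 50.0 * np.sin(2 * np.pi * 10 * t), clean.sampling_rate)
        cfg = DetectionConfig()
        ref = detect_spikes(bandpass(clean, cfg), cfg, sigma=1.0)
        fixed = remove_artifact_spectral(dirty, [10.0], halfwidth=0.5)
        got = detect_spikes(bandpass(fixed, cfg), cfg, sigma=1.0)
        tol = 2.0 / clean.sampling_rate
        matched = sum(np.min(np.abs(got.spike_times - t0)) <= tol
                      for t0 in ref.spike_times)
        assert matched / ref.n_spikes >= 0.95


class TestSNR:
    def test_hand_computed_two_waveform_cluster(self):
        w = np.array([[0.0, 4.0, 0.0], [0.0, 6.0, 0.0]])
        cluster = WaveformCluster(np.array([0.1, 0.2]), w, FS, pre_samples=1)
        assert compute_snr(cluster) == pytest.approx(4.330, abs=1e-3)

    def test_identical_waveforms_raise(self):
        w = np.tile([0.0, 5.0, 0.0], (3, 1))
        cluster = WaveformCluster(np.arange(3) * 0.1, w, FS, pre_samples=1)
        with pytest.raises(ValueError):
            compute_snr(cluster)

    def test_scale_invariance(self, rng):
        w = rng.normal(size=(20, 32))
        c1 = WaveformCluster(np.arange(20) * 0.01, w, FS)
        c2 = WaveformCluster(np.arange(20) * 0.01, 3.7 * w, FS)
        assert compute_snr(c2) == pytest.approx(compute_snr(c1), rel=1e-12)


class TestIO:
    def test_binary_round_trip(self, tmp_path, rng):
        rec = ContinuousRecording(rng.normal(size=1000).astype(np.float32), FS, "chA")
        path = tmp_path / "trace.bin"
        rec.save(path)
        back = ContinuousRecording.load(path)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-7)
        assert back.sampling_rate == FS and back.channel_id == "chA"
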