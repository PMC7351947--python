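"""Wavelet event detector and movie trace extractor."""

import numpy as np
import pytest

from gevisim.detect import (
    detect_from_movie,
    extract_trace,
    modwt_mra,
    reconstruct_band,
    wavelet_detect,
)
from gevisim.evaluate import SimConfigLike, simulate_scene, spike_iou
from gevisim.indicator import params_from_sensitivity, voltage_to_fluorescence
from gevisim.synth import SpikeTrain, assemble_recording, generate_footprint, generate_voltage_trace


def tonic_trace(T=4000, rate_hz=5.0, frame_rate=400.0, snr=10.0, noise_sd=0.1, seed=0):
    """Regular tonic spiking plus white noise; amplitude = snr * noise_sd."""
    rng = np.random.default_rng(seed)
    period = int(frame_rate / rate_hz)
    spikes = np.arange(period, T - 10, period)
    from gevisim.synth import spike_waveform

    w = spike_waveform()
    x = np.zeros(T)
    for s in spikes:
        x[s - 2 : s - 2 + w.size] = np.maximum(x[s - 2 : s - 2 + w.size], w)
    x *= snr * noise_sd
    x += rng.normal(0, noise_sd, T)
    return x, spikes


class TestMODWT:
    def test_round_trip_energy_preservation(self):
        rng = np.random.default_rng(0)
        for n in (250, 256, 4000):  # including lengths needing padding
            x = rng.normal(size=n)
            comps = modwt_mra(x)
            assert np.allclose(np.sum(comps, axis=0), x, atol=1e-8)
            assert all(c.size == n for c in comps)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="64"):
            modwt_mra(np.zeros(50))

    def test_band_excludes_slow_and_fast(self):
        t = np.arange(4096) / 400.0
        slow = np.sin(2 * np.pi * 0.5 * t)  # 0.5 Hz: below level-6 detail
        mid = np.sin(2 * np.pi * 12.0 * t)  # 12 Hz: inside levels 3-6
        assert np.std(reconstruct_band(slow)) < 0.15 * np.std(slow)
        assert np.std(reconstruct_band(mid)) > 0.7 * np.std(mid)


class TestWaveletDetect:
    def test_tonic_spiking_full_recall_no_extras(self):
        x, spikes = tonic_trace(seed=1)
        det = wavelet_detect(x)
        assert len(det) == len(spikes)
        assert np.all(np.min(np.abs(det.spike_frames[:, None] - spikes[None, :]), axis=1) <= 2)

    def test_constant_trace_yields_nothing(self):
        det = wavelet_detect(np.full(1000, 3.0))
        assert len(det) == 0

    def test_scale_invariance(self):
        x, _ = tonic_trace(seed=2)
        a = wavelet_detect(x)
        b = wavelet_detect(1000.0 * x)
        assert np.array_equal(a.spike_frames, b.spike_frames)

    def test_white_noise_null_threshold_false_event_rate(self):
        # with a 99.9th-percentile null threshold, expect <= ~0.1% of samples as events
        rng = np.random.default_rng(3)
        n_events, n_samples = 0, 0
        for s in range(5):
            x = rng.normal(size=4000)
            det = wavelet_detect(x, threshold_mode="null", null_percentile=99.9, n_null=10, null_seed=s)
            n_events += len(det)
            n_samples += x.size
        assert n_events / n_samples <= 0.002

    def test_matched_snr_polarity_agnostic(self):
        """The same threshold finds matched-SNR events for both polarities.

        Build one spiking voltage trace, map it through positive- and
        negative-going indicators of equal sensitivity, add identical
        fluorescence noise, form each polarity's own ΔF/F against its resting
        baseline, sign-correct the negative one, and detect with one
        threshold: the recovered event sets must agree.
        """
        rng = np.random.default_rng(4)
        spikes = SpikeTrain(np.arange(80, 3900, 80), 400.0, 4000)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.0, seed=0)
        noise = rng.normal(0, 1.0, 4000)  # same F-domain noise for both
        results = {}
        for pol in ("positive", "negative"):
            ind = params_from_sensitivity(pol, 100.0, 0.5)
            f = voltage_to_fluorescence(vt, ind).f + noise
            f0 = ind.F_min if pol == "positive" else ind.F_max
            dff = (f - f0) / f0
            x = dff if pol == "positive" else -dff
            results[pol] = wavelet_detect(x)
        assert np.array_equal(results["positive"].spike_frames, results["negative"].spike_frames)
        assert len(results["positive"]) > 0

    def test_short_trace_error_names_minimum(self):
        with pytest.raises(ValueError, match="64"):
            wavelet_detect(np.zeros(40))

    def test_scores_meet_threshold(self):
        x, _ = tonic_trace(seed=5)
        det = wavelet_detect(x, threshold=5.0)
        assert np.all(det.scores >= 5.0)


class TestExtractTrace:
    def _single_neuron_recording(self, polarity="positive", noise=0.0, seed=0, n_bg=0):
        cfg = SimConfigLike(n_frames=4000, mean_spikes=10, noise_coeff=noise,
                            n_background_per_target=n_bg, bleach_tau_frames=np.inf)
        return simulate_scene(1, 0.5, polarity, cfg, seed)

    def test_noiseless_trace_matches_truth(self):
        rec = self._single_neuron_recording()
        vt, fp, ind = rec.neurons[0]
        tr = extract_trace(rec, fp, "positive")
        truth = voltage_to_fluorescence(vt, ind).f
        corr = np.corrcoef(tr.f, truth)[0, 1]
        assert corr > 1 - 1e-9

    def test_refinement_beats_imperfect_roi_mean(self):
        """Starting from a crude (blurred, offset) seed ROI, weight refinement
        should recover a trace closer to the truth than the plain ROI mean."""
        from scipy import ndimage

        from gevisim.synth import SpatialFootprint

        deltas = []
        for seed in range(4):
            cfg = SimConfigLike(n_frames=4000, mean_spikes=10, noise_coeff=0.3,
                                bleach_tau_frames=np.inf)
            rec = simulate_scene(1, 1.0, "positive", cfg, seed)
            vt, fp, ind = rec.neurons[0]
            truth = voltage_to_fluorescence(vt, ind).f
            crude_w = ndimage.gaussian_filter(np.roll(fp.weights, (1, 1), axis=(0, 1)), 2.0)
            crude = SpatialFootprint(weights=crude_w, centroid=fp.centroid)
            refined = extract_trace(rec, crude, "positive", n_iter=3)
            roi = extract_trace(rec, crude, "positive", n_iter=0)
            deltas.append(np.corrcoef(refined.f, truth)[0, 1] - np.corrcoef(roi.f, truth)[0, 1])
        assert np.mean(deltas) > 0, deltas

    def test_negative_polarity_inverted_internally(self):
        rec = self._single_neuron_recording(polarity="negative")
        vt, fp, ind = rec.neurons[0]
        tr = extract_trace(rec, fp, "negative")
        truth = voltage_to_fluorescence(vt, ind).f
        assert np.corrcoef(tr.f, truth)[0, 1] > 0.99  # returned in native polarity

    def test_no_overlap_rejected(self):
        rec = self._single_neuron_recording()
        zero_fp = generate_footprint((40, 40), (20.0, 20.0), 3.0)
        zero_fp.weights = np.zeros_like(zero_fp.weights)
        with pytest.raises(ValueError):
            extract_trace(rec, zero_fp, "positive")


class TestDetectFromMovie:
    def test_noiseless_end_to_end_exact(self):
        cfg = SimConfigLike(n_frames=4000, mean_spikes=10, noise_coeff=0.0,
                            n_background_per_target=0, bleach_tau_frames=10_000.0)
        rec = simulate_scene(1, 0.2, "positive", cfg, 1)
        vt, fp, _ = rec.neurons[0]
        det = detect_from_movie(rec, fp, "positive")
        assert np.array_equal(det.spike_frames, vt.spikes.frames)

    def test_determinism(self):
        cfg = SimConfigLike(n_frames=4000, mean_spikes=10, noise_coeff=0.3)
        rec = simulate_scene(1, 1.0, "positive", cfg, 5)
        _vt, fp, _ = rec.neurons[0]
        a = detect_from_movie(rec, fp, "positive")
        b = detect_from_movie(rec, fp, "positive")
        assert np.array_equal(a.spike_frames, b.spike_frames)
        assert np.array_equal(a.scores, b.scores)

    def test_error_grows_with_noise(self):
        # recall/precision should degrade as proportional noise increases
        errs = []
        for noise in (0.05, 0.3, 0.9):
            vals = []
            for seed in (0, 1, 2):
                cfg = SimConfigLike(n_frames=4000, mean_spikes=10, noise_coeff=noise)
                rec = simulate_scene(1, 0.5, "positive", cfg, seed)
                vt, fp, _ = rec.neurons[0]
                det = detect_from_movie(rec, fp, "positive")
                ev = spike_iou(vt.spikes, SpikeTrain(det.spike_frames, 400.0, cfg.n_frames))
                vals.append(ev.error_rate)
            errs.append(np.mean(vals))
        assert errs[0] <= errs[1] + 0.05
        assert errs[1] <= errs[2] + 0.05
        assert errs[2] > errs[0]
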