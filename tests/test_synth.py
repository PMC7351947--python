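"""Synthetic-data generators: calibration, determinism, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gevisim.indicator import params_from_sensitivity
from gevisim.synth import (
    assemble_recording,
    bleach_curve,
    generate_background_neurons,
    generate_footprint,
    generate_spike_train,
    generate_voltage_trace,
)


class TestSpikeTrain:
    def test_mean_count_calibrated(self):
        # over many seeds the empirical mean count must sit within 3 SE of target
        counts = [len(generate_spike_train(4000, 400.0, 10, seed=s)) for s in range(600)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 10) < 3 * se + 1e-9, f"mean {mean:.3f}, se {se:.3f}"

    def test_zero_rate_gives_empty_train(self):
        assert len(generate_spike_train(4000, 400.0, 0, seed=1)) == 0

    def test_refractory_period_enforced(self):
        st_ = generate_spike_train(40_000, 400.0, 400, refractory_frames=4, seed=3)
        assert len(st_) > 100
        assert np.diff(st_.frames).min() > 4

    def test_deterministic_in_seed(self):
        a = generate_spike_train(4000, 400.0, 10, seed=5)
        b = generate_spike_train(4000, 400.0, 10, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_spike_train(0, 400.0, 10)
        with pytest.raises(ValueError):
            generate_spike_train(4000, 400.0, 10, refractory_frames=0)
        with pytest.raises(ValueError):
            generate_spike_train(3, 400.0, 1, refractory_frames=4)


class TestVoltageTrace:
    def test_single_spike_is_unit_peak_waveform(self, spike_train):
        from gevisim.synth import SpikeTrain

        spikes = SpikeTrain(np.array([100]), 400.0, 4000)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.0, seed=0)
        assert vt.v[100] == pytest.approx(1.0)
        assert vt.v.max() == pytest.approx(1.0)
        assert np.argmax(vt.v) == 100
        assert vt.v[:95].max() == 0.0
        assert vt.v[130:].max() == 0.0

    def test_close_spikes_collapse_by_maximum(self):
        from gevisim.synth import SpikeTrain

        spikes = SpikeTrain(np.array([100, 101]), 400.0, 4000)
        vt = generate_voltage_trace(spikes, ap_width_frames=5, subthreshold_sd=0.0, seed=0)
        assert vt.v.max() == pytest.approx(1.0)

    def test_subthreshold_sd_matches_target(self):
        from gevisim.synth import SpikeTrain

        spikes = SpikeTrain(np.empty(0, dtype=int), 400.0, 200_000)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.1, subthreshold_tau_frames=40, seed=2)
        assert vt.v.std() == pytest.approx(0.1, rel=0.05)

    def test_rest_level_zero(self):
        from gevisim.synth import SpikeTrain

        spikes = SpikeTrain(np.empty(0, dtype=int), 400.0, 50_000)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.05, seed=4)
        assert abs(vt.v.mean()) < 0.01


class TestFootprints:
    def test_unit_sum_and_centroid(self):
        fp = generate_footprint((64, 64), (32.0, 32.0), radius_px=3.0)
        assert fp.weights.sum() == pytest.approx(1.0)
        rr, cc = np.mgrid[0:64, 0:64]
        r0 = (rr * fp.weights).sum()
        c0 = (cc * fp.weights).sum()
        assert abs(r0 - 32) < 0.1 and abs(c0 - 32) < 0.1

    def test_centroid_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            generate_footprint((64, 64), (70.0, 32.0), radius_px=3.0)

    def test_deterministic(self):
        a = generate_footprint((40, 40), (20.0, 17.0), 3.0, seed=1)
        b = generate_footprint((40, 40), (20.0, 17.0), 3.0, seed=1)
        assert np.array_equal(a.weights, b.weights)

    def test_background_neurons_count_blur_and_shuffle(self, footprint, spike_train):
        bgs = generate_background_neurons(footprint, spike_train, n_background=5, blur_px=6.0, seed=9)
        assert len(bgs) == 5
        base_moment = footprint.second_moment()
        for vt, fp in bgs:
            assert not fp.in_focus
            assert fp.second_moment() > base_moment  # defocus widens the footprint
            assert len(vt.spikes) == len(spike_train)  # shuffling preserves count
        # shuffled trains differ from the source
        assert any(not np.array_equal(vt.spikes.frames, spike_train.frames) for vt, _ in bgs)

    def test_no_background_requested(self, footprint, spike_train):
        assert generate_background_neurons(footprint, spike_train, n_background=0, blur_px=6.0, seed=0) == []


class TestAssembly:
    def test_noiseless_single_neuron_identity(self, voltage_trace, footprint):
        ind = params_from_sensitivity("positive", 100.0, 0.2)
        rec = assemble_recording([(voltage_trace, footprint)], [], ind,
                                 bleach_tau_frames=np.inf, noise_coeff=0.0, seed=0, dtype=float)
        from gevisim.indicator import voltage_to_fluorescence

        f = voltage_to_fluorescence(voltage_trace, ind).f
        expected = f[:, None, None] * footprint.weights[None]
        assert np.allclose(rec.movie, expected)

    def test_conservation_noiseless(self, voltage_trace, footprint, spike_train):
        ind = params_from_sensitivity("positive", 100.0, 1.0)
        bgs = generate_background_neurons(footprint, spike_train, 3, blur_px=5.0, seed=2)
        rec = assemble_recording([(voltage_trace, footprint)], bgs, ind,
                                 bleach_tau_frames=5000.0, noise_coeff=0.0, seed=0, dtype=float)
        from gevisim.indicator import voltage_to_fluorescence

        units = [(voltage_trace, footprint)] + bgs
        total = np.zeros(rec.n_frames)
        for vt, fp in units:
            total += voltage_to_fluorescence(vt, ind).f * rec.bleach_curve * fp.weights.sum()
        assert np.allclose(rec.movie.sum(axis=(1, 2)), total, rtol=1e-5)

    def test_bleach_curve_decay_recovered(self):
        from gevisim.synth import SpikeTrain
        from gevisim.traces import fit_bleach

        spikes = SpikeTrain(np.empty(0, dtype=int), 400.0, 4000)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.0, seed=0)
        fp = generate_footprint((20, 20), (10.0, 10.0), 3.0)
        ind = params_from_sensitivity("positive", 100.0, 0.2)
        rec = assemble_recording([(vt, fp)], [], ind, bleach_tau_frames=5000.0,
                                 noise_coeff=0.0, seed=0, dtype=float)
        mean_intensity = rec.movie.mean(axis=(1, 2))
        _, fit = fit_bleach(mean_intensity)
        assert fit.tau == pytest.approx(5000.0, rel=0.02)

    def test_noise_sd_proportional_to_signal(self):
        # constant-signal recording: per-pixel sample SD must be ~ coeff * signal
        from gevisim.synth import SpikeTrain

        T = 10_000
        spikes = SpikeTrain(np.empty(0, dtype=int), 400.0, T)
        vt = generate_voltage_trace(spikes, subthreshold_sd=0.0, seed=0)
        fp = generate_footprint((16, 16), (8.0, 8.0), 4.0)
        ind = params_from_sensitivity("positive", 100.0, 0.2)
        rec = assemble_recording([(vt, fp)], [], ind, bleach_tau_frames=np.inf,
                                 noise_coeff=0.1, seed=3, dtype=float,
                                 background_offset=5.0)
        signal = ind.F_min * fp.weights + 5.0
        sd = rec.movie.std(axis=0)
        bright = signal > 5.5  # avoid pixels where zero-clipping bites
        ratio = sd[bright] / (0.1 * signal[bright])
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_seed_determinism_and_nonnegativity(self, voltage_trace, footprint):
        ind = params_from_sensitivity("negative", 100.0, 1.0)
        kw = dict(bleach_tau_frames=8000.0, noise_coeff=0.3, seed=12)
        a = assemble_recording([(voltage_trace, footprint)], [], ind, **kw)
        b = assemble_recording([(voltage_trace, footprint)], [], ind, **kw)
        assert np.array_equal(a.movie, b.movie)
        assert a.movie.min() >= 0
        assert np.all(np.diff(a.bleach_curve) <= 0) and a.bleach_curve[0] == 1.0

    def test_mismatched_lengths_rejected(self, voltage_trace, footprint):
        from gevisim.synth import SpikeTrain

        ind = params_from_sensitivity("positive", 100.0, 0.2)
        other = generate_voltage_trace(SpikeTrain(np.array([5]), 400.0, 2000), seed=0)
        with pytest.raises(ValueError):
            assemble_recording([(voltage_trace, footprint), (other, footprint)], [], ind)


@given(tau=st.floats(min_value=100.0, max_value=1e6))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_bleach_curve_monotone_from_one(tau):
    c = bleach_curve(500, tau)
    assert c[0] == 1.0
    assert np.all(np.diff(c) <= 0)
    assert np.all(c > 0)
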