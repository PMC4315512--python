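"""Sliding-window detection, location histograms and double consistency."""

import numpy as np
import pytest

import frispike as fs
from tests.conftest import draw_times


def _dirac_samples(tk, ak, cfg, n_range):
    return fs.sample_diracs(fs.DiracStream(tk, ak), cfg.kernel, cfg.T, n_range=n_range)


class TestSlidingWindowDetect:
    def test_noiseless_single_dirac_exact_in_full_capture_windows(self):
        T, t1 = 0.25, 2.37
        cfg = fs.WindowConfig(N=16, T=T, fixed_K=1, P=5, cadzow_iterations=0, method="prony")
        y = _dirac_samples([t1], [1.0], cfg, (-5, 40))
        ests = fs.sliding_window_detect(y, cfg)
        full = [t for e in ests for t, b in zip(e.times, e.border) if not b]
        assert len(full) > 0
        assert max(abs(t - t1) for t in full) < 1e-6

    def test_border_dirac_perturbs_only_nearby_windows(self):
        # a Dirac just left of a window contaminates it, but windows starting
        # >= L samples past the Dirac are exact again
        T = 0.25
        cfg = fs.WindowConfig(N=16, T=T, fixed_K=1, P=5, cadzow_iterations=0, method="prony")
        L = cfg.footprint
        t1 = 3.0
        y = _dirac_samples([t1], [1.0], cfg, (0, 60))
        ests = fs.sliding_window_detect(y, cfg)
        for e in ests:
            if e.window_index >= t1 / T:  # window fully past the Dirac footprint
                continue
            if e.window_index + 1 >= t1 / T - cfg.N + L:
                # windows whose span fully captures the Dirac: exact
                if e.times.size and not e.border.any():
                    assert abs(e.times[0] - t1) < 1e-6

    def test_all_zero_stream_yields_no_estimates(self):
        cfg = fs.WindowConfig(N=16, T=0.25, fixed_K=1, P=5)
        y = fs.SampleSequence(values=np.zeros(50), T=0.25)
        assert fs.sliding_window_detect(y, cfg) == []

    def test_too_short_input_rejected(self):
        cfg = fs.WindowConfig(N=16, T=0.25, fixed_K=1, P=5)
        y = fs.SampleSequence(values=np.ones(10), T=0.25)
        with pytest.raises(ValueError):
            fs.sliding_window_detect(y, cfg)

    def test_histogram_count_bounded_by_windows_times_kmax(self, rng):
        cfg = fs.WindowConfig(N=32, T=1 / 16, K_max=3, P=9, cadzow_iterations=0)
        tk = draw_times(rng, 3, 1.0, 5.0, 0.8)
        y = _dirac_samples(tk, np.ones(3), cfg, (0, 120))
        yn = fs.add_noise(y, 15.0, seed=1)
        ests = fs.sliding_window_detect(yn, cfg)
        hist = fs.build_histogram(ests, cfg.T / 4)
        assert hist.total <= len(ests) * cfg.K_max


class TestHistogram:
    def test_identical_locations_fall_in_one_bin(self):
        e = fs.WindowEstimate(window_index=0, times=np.full(7, 1.003),
                              amplitudes=np.ones(7), K=1,
                              border=np.zeros(7, bool), u_moduli=np.ones(7))
        hist = fs.build_histogram([e], bin_width=0.1)
        assert hist.counts.max() == 7
        assert np.count_nonzero(hist.counts) == 1

    def test_empty_estimates_give_zero_histogram(self):
        hist = fs.build_histogram([], bin_width=0.1, t_max_consistent=1.0)
        assert hist.total == 0

    def test_consistency_horizon_excludes_late_estimates(self):
        e = fs.WindowEstimate(window_index=0, times=np.array([0.5, 2.5]),
                              amplitudes=np.ones(2), K=2,
                              border=np.zeros(2, bool), u_moduli=np.ones(2))
        hist = fs.build_histogram([e], bin_width=0.25, t_max_consistent=1.0)
        assert hist.total == 1


class TestExtractPeaks:
    def _hist(self, counts, bw=0.25):
        edges = bw * np.arange(len(counts) + 1)
        return fs.LocationHistogram(bin_edges=edges, counts=np.asarray(counts))

    def test_single_sharp_peak(self):
        hist = self._hist([0, 0, 9, 0, 0])
        spikes = fs.extract_peaks(hist, 0.3, 0.5, max_count_per_event=10)
        assert len(spikes) == 1
        assert spikes.times[0] == pytest.approx(hist.centers[2])

    def test_close_peaks_merge_to_weighted_centroid(self):
        hist = self._hist([0, 6, 0, 3, 0])
        spikes = fs.extract_peaks(hist, 0.1, min_separation=1.0, max_count_per_event=10)
        assert len(spikes) == 1
        expected = (6 * hist.centers[1] + 3 * hist.centers[3]) / 9
        assert spikes.times[0] == pytest.approx(expected)

    def test_uniform_noise_floor_below_threshold_yields_nothing(self):
        hist = self._hist([2, 2, 2, 2, 2])
        spikes = fs.extract_peaks(hist, 0.5, 0.5, max_count_per_event=10)
        assert len(spikes) == 0


class TestDetectStream:
    def test_fig11_regime_top5_peaks_near_truth(self, rng):
        # SNR 15 dB, N=50, T=1/16, 5 events: local innovation rate 3.2
        T, N = 1 / 16, 50
        cfg = fs.WindowConfig(N=N, T=T, K_max=5, P=13)
        hits = 0
        trials = 8
        for _ in range(trials):
            tk = draw_times(rng, 5, 1.0, 8.5, 0.7)
            # the stream is observed from before the first event so every
            # event gets the full complement of capturing windows
            y = _dirac_samples(tk, np.ones(5), cfg, (-60, 165))
            yn = fs.add_noise(y, 15.0, seed=rng)
            spikes, hist, _ = fs.detect_stream(yn, cfg)
            if len(spikes) < 5:
                continue
            top = np.sort(spikes.times[np.argsort(spikes.amplitudes)[::-1][:5]])
            if np.all(np.abs(top[:, None] - tk[None, :]).min(axis=1) <= hist.bin_width):
                hits += 1
        assert hits / trials >= 0.75

    def test_shift_invariance_of_detection(self):
        # shifting the input by j samples shifts the detected spikes by j*T
        T, j = 1 / 8, 5
        cfg = fs.WindowConfig(N=24, T=T, fixed_K=1, P=5, cadzow_iterations=0, method="prony")
        tk = np.array([2.3])
        y = _dirac_samples(tk, [1.0], cfg, (0, 80))
        ys = _dirac_samples(tk + j * T, [1.0], cfg, (j, 80 + j))
        s1, _, _ = fs.detect_stream(y, cfg)
        s2, _, _ = fs.detect_stream(ys, cfg)
        assert len(s1) == len(s2) == 1
        assert abs((s2.times[0] - s1.times[0]) - j * T) < 1e-9


class TestDoubleConsistency:
    T = 1 / 16

    def _configs(self):
        big = fs.WindowConfig(N=32, T=self.T, K_max=4, cadzow_iterations=10)
        small = fs.WindowConfig(N=8, T=self.T, fixed_K=1, P=5, cadzow_iterations=10)
        return big, small

    def test_noiseless_single_transient_recovered_within_one_bin(self):
        big, small = self._configs()
        model = fs.CalciumModel(A=1.0, tau_ca=0.5)
        trace, _ = fs.gen_calcium_trace(fs.SpikeTrain(np.array([2.0])), model, self.T, 160)
        train, hist, _ = fs.double_consistency(trace, big, small, model.alpha, A=model.A)
        assert len(train) == 1
        assert abs(train.times[0] - 2.0) <= hist.bin_width

    def test_config_roles_enforced(self):
        big, small = self._configs()
        trace = fs.SampleSequence(values=np.zeros(100), T=self.T)
        with pytest.raises(ValueError):
            fs.double_consistency(trace, big, big, 2.0)
        with pytest.raises(ValueError):
            fs.double_consistency(trace, small, small, 2.0)

    def test_noisy_calcium_count_and_timing(self, rng):
        big, small = self._configs()
        ok_count = ok_time = trials = 0
        for _ in range(8):
            base = fs.gen_poisson_spikes(0.4, 8.0, refractory=0.6, seed=rng)
            spikes = fs.SpikeTrain(base.times + 1.0)
            if len(spikes) == 0:
                continue
            trials += 1
            model = fs.CalciumModel(A=1.0, tau_ca=0.5, snr_db=20.0)
            trace, _ = fs.gen_calcium_trace(spikes, model, self.T, 176, seed=rng)
            train, _, _ = fs.double_consistency(trace, big, small, model.alpha, A=model.A)
            if len(train) == len(spikes):
                ok_count += 1
                if np.max(np.abs(np.sort(train.times) - spikes.times)) <= 2 * self.T:
                    ok_time += 1
        assert trials >= 4
        assert ok_count / trials > 0.5
        assert ok_time / trials > 0.5

    def test_window_size_change_moves_peaks_less_than_a_bin(self):
        big, small = self._configs()
        big2 = fs.WindowConfig(N=64, T=self.T, K_max=4, cadzow_iterations=10)
        small2 = fs.WindowConfig(N=16, T=self.T, fixed_K=1, P=5, cadzow_iterations=10)
        model = fs.CalciumModel(A=1.0, tau_ca=0.5)
        spikes = fs.SpikeTrain(np.array([2.0, 5.0]))
        trace, _ = fs.gen_calcium_trace(spikes, model, self.T, 176)
        t1, h1, _ = fs.double_consistency(trace, big, small, model.alpha, A=model.A)
        t2, h2, _ = fs.double_consistency(trace, big2, small2, model.alpha, A=model.A)
        assert len(t1) == len(t2) == 2
        assert np.max(np.abs(t1.times - t2.times)) <= h1.bin_width
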