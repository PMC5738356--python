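"""Firing statistics, error metrics, replay classifier, eigenspectra and
the convergence-fit machinery."""

import numpy as np
import pytest

from spikeforce import metrics as M
from spikeforce import supervisors as sup
from spikeforce.synapses import build_static_weights, build_encoders


def _raster(times, ids, N, window, unit="ms"):
    return M.SpikeRaster(np.asarray(times, float), np.asarray(ids), N,
                         window, unit=unit)


class TestMeanRate:
    def test_arithmetic_definition(self):
        # 2000 neurons, 5 s, 229000 spikes -> 22.9 Hz
        rng = np.random.default_rng(0)
        n = 229000
        r = _raster(rng.uniform(0, 5000, n), rng.integers(0, 2000, n),
                    2000, (0.0, 5000.0))
        assert M.mean_firing_rate(r) == pytest.approx(22.9)

    def test_empty_raster(self):
        r = _raster([], [], 10, (0.0, 100.0))
        assert M.mean_firing_rate(r) == 0.0

    def test_window_validation(self):
        r = _raster([5.0], [0], 2, (0.0, 10.0))
        with pytest.raises(ValueError):
            M.mean_firing_rate(r, window=(3.0, 3.0))
        with pytest.raises(ValueError):
            M.mean_firing_rate(r, window=(0.0, 20.0))


class TestISI:
    def test_periodic_train_cv_zero(self):
        r = _raster(np.arange(1, 100) * 10.0, np.zeros(99, int), 1,
                    (0, 1000))
        out = M.isi_stats(r)
        assert out["cv"][0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(42)
        # homogeneous Poisson at 20 Hz, 1e4 spikes
        isis = rng.exponential(50.0, size=10000)
        times = np.cumsum(isis)
        r = _raster(times, np.zeros(times.size, int), 1, (0, times[-1] + 1))
        out = M.isi_stats(r)
        assert abs(out["cv"][0] - 1.0) < 0.05

    def test_bimodal_detection_and_exclusions(self):
        times = np.concatenate([np.cumsum(np.full(50, 5.0)),
                                1000 + np.cumsum(np.full(50, 100.0))])
        ids = np.zeros(100, int)
        r = _raster(np.sort(times), ids, 2, (0, 7000))
        out = M.isi_stats(r, bins=30)
        hist = out["hist"]
        # two well-separated occupied regions
        occupied = np.flatnonzero(hist > 0)
        assert occupied.min() < 5 and occupied.max() > 20
        assert out["n_excluded"] == 0  # neuron 1 has no spikes at all


class TestErrors:
    def test_l2_identities(self):
        t = np.linspace(0, 1, 101)
        x = np.sin(t)[:, None]
        assert M.l2_error(x, x) == 0.0
        assert M.l2_error(x + 0.3, x) == pytest.approx(0.3)
        assert M.l2_error(x + 0.2, x) * 5 == pytest.approx(
            M.l2_error(x + 1.0, x), rel=1e-9)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            M.l2_error(np.zeros((5, 1)), np.zeros((6, 1)))

    def test_correlation_identities(self, rng):
        x = rng.normal(size=(200, 3))
        assert M.time_avg_correlation(x, x) == pytest.approx(1.0)
        assert M.time_avg_correlation(-x, x) == pytest.approx(-1.0)

    def test_correlation_noise_component(self, rng):
        x = rng.normal(size=(5000, 4))
        xhat = x.copy()
        xhat[:, 0] = rng.normal(size=5000)
        r = M.time_avg_correlation(xhat, x)
        assert r == pytest.approx(0.75, abs=0.03)

    def test_correlation_all_constant_raises(self):
        with pytest.raises(ValueError):
            M.time_avg_correlation(np.ones((10, 2)), np.ones((10, 2)))


class TestReplayClassifier:
    def _song(self):
        return sup.note_song(sup.ODE_TO_JOY_BAR1)

    def test_perfect_tiling_fraction_one(self):
        song = self._song()
        dt = 0.005
        t = np.arange(0, 10.0, dt)
        xhat = song(t)  # periodic tiling by construction
        rep = M.replay_classifier(t, xhat, song)
        assert rep.fraction_correct_duration == pytest.approx(1.0, abs=0.02)
        assert rep.n_correct == 10  # one replay per period of the scan

    def test_shifted_copy_single_minimum(self):
        song = self._song()
        dt = 0.005
        t = np.arange(0, 2.0, dt)
        xhat = np.zeros((t.size, 5))
        mask = t >= 0.5
        xhat[mask] = song(t[mask] - 0.5)
        rep = M.replay_classifier(t, xhat, song)
        assert rep.n_correct == 1
        assert rep.replay_times[0] == pytest.approx(0.5, abs=0.02)

    def test_noise_yields_no_replays(self, rng):
        song = self._song()
        t = np.arange(0, 10.0, 0.005)
        xhat = rng.normal(scale=10.0, size=(t.size, 5))
        rep = M.replay_classifier(t, xhat, song)
        assert rep.n_correct == 0

    def test_bad_threshold_raises(self):
        song = self._song()
        t = np.arange(0, 4.0, 0.01)
        with pytest.raises(ValueError):
            M.replay_classifier(t, song(t), song, threshold=-1.0)


class TestEigenspectrum:
    def test_circular_law_radius(self):
        N, p, G = 500, 0.1, 2.0
        w = build_static_weights(N, p, model="izhikevich", seed=0,
                                 variance="np")
        lam = M.eigenspectrum(G * w.toarray())
        # dense-equivalent entry variance p·σ² = 1/N  ->  radius ≈ G
        assert np.abs(lam).max() == pytest.approx(G, rel=0.15)

    def test_rank_bound_of_feedback_term(self, rng):
        N, m = 60, 2
        eta = build_encoders(N, m, seed=1)
        phi = rng.normal(size=(N, m))
        lam = M.eigenspectrum(5.0 * eta @ phi.T)
        assert (np.abs(lam) > 1e-8).sum() <= m

    def test_symmetric_matrix_real_spectrum(self, rng):
        A = rng.normal(size=(30, 30))
        lam = M.eigenspectrum(A + A.T)
        assert np.abs(lam.imag).max() < 1e-9

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            M.eigenspectrum(np.zeros((3, 4)))


class TestConvergenceFit:
    def test_exact_power_law_recovered(self):
        N = np.array([250, 500, 1000, 2000, 4000])
        errs = 7.3 / np.sqrt(N)
        assert M.fit_power_law(N, errs) == pytest.approx(-0.5, abs=1e-12)

    def test_runner_interface_and_bootstrap(self):
        def runner(N, seed):
            rng = np.random.default_rng(seed)
            return 3.0 / N * np.exp(rng.normal(0, 0.02))
        out = M.convergence_experiment("synthetic",
                                       N_list=[100, 200, 400, 800],
                                       reps=3, runner=runner, seed=0)
        assert out["slope"] == pytest.approx(-1.0, abs=0.05)
        lo, hi = out["slope_ci"]
        assert lo <= -1.0 <= hi or abs(out["slope"] + 1) < 0.05

    def test_failures_recorded_not_fatal(self):
        def runner(N, seed):
            if N == 200:
                raise RuntimeError("boom")
            return 1.0 / N
        out = M.convergence_experiment("synthetic",
                                       N_list=[100, 200, 400, 800],
                                       reps=1, runner=runner)
        assert len(out["failures"]) == 1
        assert np.isfinite(out["slope"])


class TestPopulationActivity:
    def test_modulated_raster_dominant_frequency(self, rng):
        # 4 Hz-modulated inhomogeneous Poisson raster
        T, N = 5000.0, 100
        t_grid = np.arange(0, T, 1.0)
        lam = 0.02 * (1 + 0.9 * np.sin(2 * np.pi * 0.004 * t_grid))
        counts = rng.poisson(lam[None, :].repeat(N, 0))
        ids, bins = np.nonzero(counts)
        r = _raster(t_grid[bins], ids, N, (0, T))
        out = M.mean_population_activity(r, bin_width=10.0)
        assert out["dominant_freq_hz"] == pytest.approx(4.0, abs=0.5)

    def test_flat_poisson_no_dominant_peak(self, rng):
        T, N = 5000.0, 100
        times = rng.uniform(0, T, 40000)
        ids = rng.integers(0, N, 40000)
        out = M.mean_population_activity(_raster(times, ids, N, (0, T)),
                                         bin_width=10.0)
        assert out["peak_power"] < 20 * out["noise_floor"]

    def test_bin_bookkeeping(self):
        r = _raster([1.0, 2.0], [0, 0], 1, (0.0, 100.0))
        out1 = M.mean_population_activity(r, bin_width=1.0)
        out2 = M.mean_population_activity(r, bin_width=2.0)
        assert out1["rate_hz"].size == 2 * out2["rate_hz"].size
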