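"""Quantitative read-outs: firing statistics, error metrics, the moving
replay classifier, eigenspectra, chaos diagnostics, and the network-size
convergence experiment.

All metrics are pure functions of their inputs: the same raster or traces
always produce the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.signal
import scipy.sparse as sp

__all__ = [
    "SpikeRaster",
    "ReplayReport",
    "mean_firing_rate",
    "isi_stats",
    "l2_error",
    "log_l2",
    "time_avg_correlation",
    "replay_classifier",
    "eigenspectrum",
    "spike_deletion_test",
    "chaos_onset_sweep",
    "convergence_experiment",
    "fit_power_law",
    "mean_population_activity",
]


@dataclass
class SpikeRaster:
    """Spike events (neuron_id, time) over a window, times in ``unit``."""

    times: np.ndarray
    ids: np.ndarray
    N: int
    window: tuple
    unit: str = "ms"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have matching shapes")
        if self.times.size:
            if self.ids.min() < 0 or self.ids.max() >= self.N:
                raise ValueError("neuron ids must lie in [0, N)")

    @classmethod
    def from_result(cls, result, window: Optional[tuple] = None,
                    N: Optional[int] = None) -> "SpikeRaster":
        N = N if N is not None else (int(result.spike_ids.max()) + 1
                                     if result.spike_ids.size else 1)
        if window is None:
            lo = min(b[0] for b in result.phases.values())
            hi = max(b[1] for b in result.phases.values())
            window = (lo, hi)
        keep = (result.spike_times >= window[0]) \
            & (result.spike_times <= window[1])
        return cls(result.spike_times[keep], result.spike_ids[keep], N,
                   window, unit=result.time_unit)

    @property
    def unit_to_seconds(self) -> float:
        return 1e-3 if self.unit == "ms" else 1.0

    def binned(self, bin_width: float) -> np.ndarray:
        """(N, n_bins) spike counts."""
        t0, t1 = self.window
        n_bins = max(1, int(np.ceil((t1 - t0) / bin_width)))
        out = np.zeros((self.N, n_bins), dtype=np.int64)
        if self.times.size:
            b = np.clip(((self.times - t0) / bin_width).astype(int),
                        0, n_bins - 1)
            np.add.at(out, (self.ids, b), 1)
        return out


def mean_firing_rate(raster: SpikeRaster,
                     window: Optional[tuple] = None) -> float:
    """Total spikes / (N × window length), in Hz."""
    t0, t1 = window if window is not None else raster.window
    if t1 <= t0:
        raise ValueError("empty window")
    if not (raster.window[0] <= t0 and t1 <= raster.window[1]):
        raise ValueError("window outside raster window")
    n = int(np.count_nonzero((raster.times >= t0) & (raster.times <= t1)))
    dur_s = (t1 - t0) * raster.unit_to_seconds
    return n / (raster.N * dur_s)


def isi_stats(raster: SpikeRaster, bins: int = 50,
              log_bins: bool = False) -> dict:
    """Per-neuron ISI lists, CVs, and a pooled histogram.

    Neurons with fewer than two spikes are excluded from the CV (their
    count is reported).  CV = sd(ISI)/mean(ISI): 0 for a perfectly
    periodic train, ≈1 for Poisson firing.
    """
    isis = {}
    cvs = {}
    excluded = 0
    order = np.lexsort((raster.times, raster.ids))
    ids = raster.ids[order]
    times = raster.times[order]
    for i in np.unique(ids):
        ts = times[ids == i]
        if ts.size < 2:
            excluded += 1
            continue
        d = np.diff(ts)
        isis[int(i)] = d
        cvs[int(i)] = float(d.std() / d.mean()) if d.mean() > 0 else np.nan
    pooled = (np.concatenate(list(isis.values())) if isis
              else np.empty(0))
    if pooled.size:
        if log_bins:
            edges = np.logspace(np.log10(max(pooled.min(), 1e-6)),
                                np.log10(pooled.max() * 1.0001), bins + 1)
        else:
            edges = np.linspace(0.0, pooled.max() * 1.0001, bins + 1)
        hist, edges = np.histogram(pooled, bins=edges)
    else:
        hist, edges = np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
    return {"isis": isis, "cv": cvs,
            "cv_mean": float(np.nanmean(list(cvs.values()))) if cvs
            else np.nan,
            "hist": hist, "edges": edges, "n_excluded": excluded}


def l2_error(xhat: np.ndarray, x: np.ndarray,
             window: Optional[np.ndarray] = None,
             normalized: bool = True,
             dt: float = 1.0) -> float:
    """√(∫|x̂-x|² dt / ∫dt) — time-averaged L2 error (the raw integral,
    without the 1/∫dt normalization, via ``normalized=False``)."""
    xhat = np.atleast_2d(np.asarray(xhat, dtype=float).T).T
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    if xhat.shape != x.shape:
        raise ValueError("misaligned traces")
    if window is not None:
        xhat, x = xhat[window], x[window]
    sq = np.sum((xhat - x) ** 2, axis=1)
    total = sq.sum() * dt
    if normalized:
        return float(np.sqrt(total / (sq.size * dt)))
    return float(np.sqrt(total))


def log_l2(xhat, x, **kwargs) -> float:
    return float(np.log(l2_error(xhat, x, **kwargs)))


def time_avg_correlation(xhat: np.ndarray, x: np.ndarray) -> float:
    """Per-component Pearson correlation over time, averaged over
    components; constant components are excluded (error if all are)."""
    xhat = np.atleast_2d(np.asarray(xhat, dtype=float).T).T
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    if xhat.shape != x.shape:
        raise ValueError("misaligned traces")
    if xhat.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rs = []
    for j in range(x.shape[1]):
        sx = x[:, j].std()
        sy = xhat[:, j].std()
        if sx == 0 or sy == 0:
            continue
        rs.append(float(np.corrcoef(xhat[:, j], x[:, j])[0, 1]))
    if not rs:
        raise ValueError("all components constant")
    return float(np.mean(rs))


@dataclass
class ReplayReport:
    """Output of the moving-error replay classifier."""

    t: np.ndarray
    E_trace: np.ndarray
    threshold: float
    replay_times: np.ndarray
    n_correct: int
    fraction_correct_duration: float


def replay_classifier(t: np.ndarray, xhat: np.ndarray,
                      supervisor, T: Optional[float] = None,
                      threshold: Optional[float] = None) -> ReplayReport:
    """Moving-average replay detection.

    E(t) = Σ_i ∫_t^{t+T} (x̂_i(t') - x_i(t' - t))² dt' slides one period of
    the teaching signal along the network output; local minima of E below a
    critical value are counted as correct replays.  The default threshold
    is 25% of the supervisor's squared power over one period.  Replays are
    located by a greedy left-to-right scan: wherever E drops below the
    threshold, the argmin of E over the next period is recorded and the
    scan jumps one period ahead, so detected replays never overlap.
    Returns the fraction of the scanned duration covered by correct
    replays.
    """
    t = np.asarray(t, dtype=float)
    xhat = np.atleast_2d(np.asarray(xhat, dtype=float).T).T
    T = T if T is not None else supervisor.T
    dt = float(np.median(np.diff(t)))
    nT = int(round(T / dt))
    if nT < 2 or xhat.shape[0] <= nT:
        raise ValueError("trace shorter than one supervisor period")
    tau = np.arange(nT) * dt
    x_ref = np.atleast_2d(supervisor(tau))
    power = float(np.sum(x_ref ** 2) * dt)
    if threshold is None:
        threshold = 0.25 * power
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    # E(t_k) = Σ_i [ Σ x̂², window ] - 2 Σ x̂·x_ref + Σ x_ref²  via correlation
    n_lag = xhat.shape[0] - nT + 1
    E = np.zeros(n_lag)
    for i in range(xhat.shape[1]):
        xi = xhat[:, i]
        sq = np.convolve(xi * xi, np.ones(nT), mode="valid")
        cross = scipy.signal.fftconvolve(xi, x_ref[::-1, i], mode="valid")
        E += sq - 2.0 * cross + np.sum(x_ref[:, i] ** 2)
    E *= dt
    tE = t[:n_lag]
    replay_times = []
    k = 0
    while k < n_lag:
        if E[k] < threshold:
            k_end = min(k + nT, n_lag)
            k_star = k + int(np.argmin(E[k:k_end]))
            replay_times.append(tE[k_star])
            k = k_star + nT
        else:
            k += 1
    n_correct = len(replay_times)
    frac = min(1.0, n_correct * T / (tE[-1] - tE[0] + dt)) if n_lag else 0.0
    return ReplayReport(t=tE, E_trace=E, threshold=float(threshold),
                        replay_times=np.asarray(replay_times),
                        n_correct=n_correct,
                        fraction_correct_duration=float(frac))


def eigenspectrum(omega: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Full complex spectrum of an effective weight matrix."""
    w = omega.toarray() if sp.issparse(omega) else np.asarray(omega)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    return np.linalg.eigvals(w)


def spike_deletion_test(neuron, weights, synapse, duration, dt,
                        t_delete: float, seed: int = 0,
                        time_unit: str = "ms", bin_width: float = 1.0,
                        decoder=None) -> dict:
    """Delete one spike and measure raster divergence.

    Runs the network once, finds the first spike at or after ``t_delete``,
    reruns with that spike untransmitted, and reports the per-bin Hamming
    distance between the binarized rasters (bin width in run units).
    """
    from . import rls  # local import to avoid a cycle

    base = rls.simulate(neuron, weights, synapse, duration, dt, seed=seed,
                        time_unit=time_unit, decoder=decoder)
    after = base.spike_times >= t_delete
    if not np.any(after):
        raise ValueError(f"no spike at or after t_delete={t_delete}")
    k = int(np.argmax(after))
    del_t = base.spike_times[k]
    del_id = int(base.spike_ids[k])
    del_step = int(round(del_t / dt))  # spike times are step_index * dt
    pert = rls.simulate(neuron, weights, synapse, duration, dt, seed=seed,
                        time_unit=time_unit, decoder=decoder,
                        delete_spike=(del_id, del_step))
    rb = SpikeRaster(base.spike_times, base.spike_ids, weights.N,
                     (0.0, duration), unit=time_unit).binned(bin_width) > 0
    rp = SpikeRaster(pert.spike_times, pert.spike_ids, weights.N,
                     (0.0, duration), unit=time_unit).binned(bin_width) > 0
    distance = np.abs(rb.astype(int) - rp.astype(int)).sum(axis=0)
    t_bins = np.arange(distance.size) * bin_width
    # tail statistics: how completely have the rasters decorrelated?
    q = 3 * distance.size // 4
    tail_mismatch = int(distance[q:].sum())
    tail_total = int(rb[:, q:].sum() + rp[:, q:].sum())
    norm_div = tail_mismatch / tail_total if tail_total else 0.0
    return {"t": t_bins, "distance": distance, "deleted_neuron": del_id,
            "deleted_time": float(del_t),
            "tail_spikes": tail_total,
            "normalized_divergence": float(norm_div),
            "base_rate_hz": base.mean_rate_hz["init"]}


def chaos_onset_sweep(model: str, G_grid: Sequence[float], trials: int = 3,
                      N: int = 500, p: float = 0.1, duration: float = 1.0,
                      dt: float = 1e-4, t_delete: Optional[float] = None,
                      time_unit: str = "s", seed: int = 0,
                      synapse=None, neuron=None,
                      divergence_threshold: float = 0.5,
                      min_tail_spikes: int = 20) -> dict:
    """Locate the onset of chaotic spiking as a function of the static gain.

    For each G, runs ``trials`` paired spike-deletion simulations.  A trial
    is chaotic when the network sustains activity into the final quarter of
    the run (at least ``min_tail_spikes`` spikes there) and the rasters
    have decorrelated: the fraction of tail spikes unmatched between the
    two runs exceeds ``divergence_threshold`` (identical runs give 0,
    fully decorrelated runs approach 1).  The onset estimate is the
    smallest G chaotic in a majority of trials; the full divergence-vs-G
    table is returned alongside (``detected`` is False when the grid lies
    entirely below onset).
    """
    from .neurons import NeuronParams
    from .synapses import SynapseParams, WeightConfig

    G_grid = sorted(G_grid)
    if neuron is None:
        neuron = {"theta": NeuronParams.theta,
                  "lif": NeuronParams.lif,
                  "izhikevich": NeuronParams.izhikevich}[model]()
    if synapse is None:
        tscale = 1e-3 if time_unit == "s" else 1.0
        synapse = SynapseParams(tau_r=2.0 * tscale, tau_d=20.0 * tscale)
    t_delete = t_delete if t_delete is not None else duration / 3.0
    bin_width = 1e-3 if time_unit == "s" else 1.0
    rows = []
    onset = None
    for G in G_grid:
        n_chaotic = 0
        divs = []
        for trial in range(trials):
            w = WeightConfig(N=N, p=p, G=G, Q=0.0,
                             seed=seed + 1000 * trial)
            try:
                out = spike_deletion_test(neuron, w, synapse, duration, dt,
                                          t_delete, seed=seed + trial,
                                          time_unit=time_unit,
                                          bin_width=bin_width)
            except ValueError:  # no spikes: quiescent at this G
                divs.append(0.0)
                continue
            divs.append(out["normalized_divergence"])
            if out["tail_spikes"] >= min_tail_spikes \
                    and out["normalized_divergence"] > divergence_threshold:
                n_chaotic += 1
        chaotic = n_chaotic > trials / 2
        rows.append({"G": G, "divergence": float(np.mean(divs)),
                     "n_chaotic": n_chaotic, "chaotic": chaotic})
        if chaotic and onset is None:
            onset = G
    return {"onset": onset, "table": rows,
            "detected": onset is not None}


def fit_power_law(N_values: Sequence[float],
                  errors: Sequence[float]) -> float:
    """Least-squares slope of log(error) vs log(N)."""
    logN = np.log(np.asarray(N_values, dtype=float))
    logE = np.log(np.asarray(errors, dtype=float))
    return float(np.polyfit(logN, logE, 1)[0])


def convergence_experiment(model: str, N_list: Sequence[int],
                           reps: int = 3,
                           supervisor=None,
                           runner: Optional[Callable] = None,
                           seed: int = 0,
                           n_boot: int = 200) -> dict:
    """Test-phase L2 error versus network size, with a log–log slope fit.

    Trains a network at each N (``reps`` seeds each) on the same
    supervisor and fits log(error) vs log(N) by least squares on the
    per-(N, rep) errors; a bootstrap over reps gives a slope CI.  Failures
    at any single size are recorded, not fatal.  ``runner(N, seed)`` can
    override the default trainer (the standard sinusoid presets for the
    given model).
    """
    if len(set(N_list)) < 3:
        raise ValueError("need at least 3 distinct N")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if runner is None:
        from .experiments import make_convergence_runner
        runner = make_convergence_runner(model, supervisor)
    errs = np.full((len(N_list), reps), np.nan)
    failures = []
    for i, N in enumerate(N_list):
        for rep in range(reps):
            try:
                errs[i, rep] = runner(int(N), seed + 7919 * rep + i)
            except Exception as exc:  # record, keep sweeping
                failures.append({"N": int(N), "rep": rep, "error": str(exc)})
    mean_err = np.nanmean(errs, axis=1)
    ok = np.isfinite(mean_err)
    slope = fit_power_law(np.asarray(N_list)[ok], mean_err[ok])
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, reps, size=reps)
        e = np.nanmean(errs[:, pick], axis=1)
        okb = np.isfinite(e)
        if okb.sum() >= 3:
            boots.append(fit_power_law(np.asarray(N_list)[okb], e[okb]))
    ci = (float(np.percentile(boots, 2.5)),
          float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    return {"N": list(N_list), "errors": errs, "mean_errors": mean_err,
            "slope": slope, "slope_ci": ci, "failures": failures}


def mean_population_activity(raster: SpikeRaster, bin_width: float) -> dict:
    """Binned population rate and its dominant frequency.

    Counts spikes per bin across the whole population, normalizes to a
    rate in Hz, and locates the spectral peak of a Hann-windowed
    periodogram, excluding DC.  Frequencies are reported in Hz.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts = raster.binned(bin_width).sum(axis=0)
    dt_s = bin_width * raster.unit_to_seconds
    rate = counts / (raster.N * dt_s)
    freqs, power = scipy.signal.periodogram(rate, fs=1.0 / dt_s,
                                            window="hann")
    if freqs.size > 1:
        k = 1 + int(np.argmax(power[1:]))
        dominant = float(freqs[k])
        peak_power = float(power[k])
        noise = float(np.median(power[1:]))
    else:
        dominant, peak_power, noise = np.nan, 0.0, 0.0
    t_bins = raster.window[0] + np.arange(counts.size) * bin_width
    return {"t": t_bins, "rate_hz": rate, "freqs": freqs, "power": power,
            "dominant_freq_hz": dominant, "peak_power": peak_power,
            "noise_floor": noise}
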