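"""Config-driven experiment presets and run orchestration.

Each preset bundles a neuron model (standard parameter set), the static
weight configuration (N, sparsity p, gains G and Q), the synaptic filter,
the supervisor and the training schedule for one of the desk-scale
benchmark experiments: the rate-network sinusoid, the spiking-oscillator
suite (theta/LIF/Izhikevich), the Lorenz system, note-song storage, the
songbird-style pulse-chain circuit and the HDTS movie-replay circuit, plus
sweep presets for the chaos-onset and network-size-convergence
experiments.

Times are in milliseconds except for the theta-model presets, which run in
seconds: the theta phase equation is dimensionless with unit intrinsic
time, and the printed theta parameter sets (feedback gain Q = 1e4 on an
O(1) supervisor, trained rates of tens of Hz, chaos onset near G = 0.02)
are consistent only when that unit is ~1 s.  Appending ``_small`` to a
preset name divides N and the phase durations by 4 for quick runs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import io, metrics, perturb, rls, supervisors
from .neurons import NeuronParams
from .rls import TrainSchedule, train, train_with_input
from .synapses import SynapseParams, WeightConfig

__all__ = [
    "PRESET_NAMES",
    "PARAMETER_MANIFEST",
    "get_preset",
    "run_preset",
    "make_fixture",
    "report",
    "make_convergence_runner",
]

# Printed parameter sets, frozen for the table-driven preset test.
# (dt/dt_rls/lam_inv in the preset's own time unit.)
PARAMETER_MANIFEST = {
    "fig1_rate": dict(N=1000, p=0.1, G=1.0, Q=1.5, F=10.0, tau_s=10.0,
                      dt_rls=2.0, lam_inv=0.5, t_init=1000.0,
                      t_train=4000.0, t_test=5000.0, unit="ms"),
    "fig2_theta_sine": dict(N=2000, p=0.1, G=10.0, Q=1e4, dt=1e-5,
                            dt_rls=5e-4, lam_inv=1e-5, unit="s"),
    "fig2_theta_sawtooth": dict(N=2000, p=0.1, G=10.0, Q=1e4, dt=1e-5,
                                dt_rls=5e-4, lam_inv=1e-5, unit="s"),
    "fig2_theta_vdp_harmonic": dict(N=2000, p=0.1, G=15.0, Q=1e4,
                                    mu=0.3, unit="s"),
    "fig2_theta_vdp_relaxation": dict(N=2000, p=0.1, G=15.0, Q=1e4,
                                      mu=5.0, unit="s"),
    "fig2_theta_product_of_sines": dict(N=2000, p=0.1, G=25.0, Q=1e4,
                                        f1=4.0, f2=6.0, unit="s"),
    "fig2_theta_product_of_sines_noise": dict(N=2000, p=0.1, G=15.0,
                                              Q=1e4, noise_sd=0.05,
                                              unit="s"),
    "fig2_lif_sine": dict(N=2000, p=0.1, G=0.04, Q=10.0, dt=5e-5,
                          dt_rls=2.5e-3, lam_inv=0.0025, I_bias=-40.0,
                          t_train=4.0, t_test=5.0, unit="s"),
    "fig2_izh_sine": dict(N=2000, p=0.1, G=5e3, Q=5e3, dt=0.04,
                          dt_rls=0.8, lam_inv=1.0, I_bias=1000.0,
                          t_train=4000.0, t_test=5000.0, unit="ms"),
    "fig2_lorenz": dict(N=5000, p=0.1, G=14.0, Q=1e4, dt=1e-5,
                        dt_rls=5e-4, lam_inv=1e-5, t_train=45.0,
                        t_test=50.0, unit="s"),
    "fig3_ode_to_joy": dict(N=5000, p=0.1, G=1e4, Q=4e3, dt=0.04,
                            dt_rls=4.0, lam_inv=2.0, T_song=4000.0,
                            t_train=900e3, t_test=1000e3, unit="ms"),
    "songbird_synthetic": dict(N=1000, p=0.1, G=1.3e4, Q=1e3, dt=0.04,
                               dt_rls=4.0, lam_inv=2.0, K=500,
                               pulse_period=20.0, w_in_scale=8e3,
                               unit="ms"),
    "hdts_replay_synthetic": dict(N=1000, p=0.1, G=5e3, Q=4e2, dt=0.04,
                                  dt_rls=4.0, lam_inv=2.0, m_hdts=8,
                                  pulse_ms=250.0, w_in_scale=4e3,
                                  n_pixels=64, unit="ms"),
}

_THETA_SYN = SynapseParams(tau_r=2e-3, tau_d=20e-3)   # seconds
_MS_SYN = SynapseParams(tau_r=2.0, tau_d=20.0)        # milliseconds


def _theta_preset(seed, scale, supervisor, G, *, t_init=5.0, t_train=5.0,
                  t_test=5.0, Q=1e4, N=2000):
    return dict(
        neuron=NeuronParams.theta(),
        weights=WeightConfig(N=max(16, N // scale), p=0.1, G=G, Q=Q,
                             seed=seed),
        synapse=_THETA_SYN,
        supervisor=supervisor,
        schedule=TrainSchedule(dt=1e-5, dt_rls=5e-4,
                               t_init=t_init / scale, t_train=t_train / scale,
                               t_test=t_test / scale, seed=seed + 1,
                               time_unit="s"),
        lam_inv=1e-5)


def _build_fig1_rate(seed, scale):
    # static std 1/(F √(Np)): the type-I transfer r = F√s amplifies
    # currents by F, so the 1/F factor keeps the chaotic fluctuations
    # commensurate with the O(1) learned feedback (Q = 1.5)
    return dict(
        neuron=NeuronParams.rate(F=10.0, tau_s=10.0),
        weights=WeightConfig(N=max(16, 1000 // scale), p=0.1, G=1.0, Q=1.5,
                             seed=seed, variance="np", scale=0.1),
        synapse=_MS_SYN,
        supervisor=supervisors.sinusoid(0.005),  # 5 Hz in ms units
        schedule=TrainSchedule(dt=0.5, dt_rls=2.0, t_init=1000.0 / scale,
                               t_train=4000.0 / scale,
                               t_test=5000.0 / scale, seed=seed + 1),
        lam_inv=0.5)


def _build_fig2_theta_sine(seed, scale):
    return _theta_preset(seed, scale, supervisors.sinusoid(5.0), G=10.0)


def _build_fig2_theta_sawtooth(seed, scale):
    return _theta_preset(seed, scale, supervisors.sawtooth(5.0), G=10.0)


def _build_fig2_theta_vdp_harmonic(seed, scale):
    return _theta_preset(seed, scale, supervisors.van_der_pol(0.3), G=15.0)


def _build_fig2_theta_vdp_relaxation(seed, scale):
    return _theta_preset(seed, scale, supervisors.van_der_pol(5.0), G=15.0)


def _build_fig2_theta_product_of_sines(seed, scale):
    # the product-of-sines target needs ~50 s of training at full scale
    return _theta_preset(seed, scale,
                         supervisors.product_of_sines(4.0, 6.0), G=25.0,
                         t_train=50.0, t_test=10.0)


def _build_fig2_theta_product_of_sines_noise(seed, scale):
    return _theta_preset(
        seed, scale,
        supervisors.product_of_sines(4.0, 6.0, noise_sd=0.05,
                                     seed=seed + 3),
        G=15.0, t_train=50.0, t_test=10.0)


def _build_fig2_lif_sine(seed, scale):
    # the LIF benchmark runs in seconds; dt = 5e-5 s resolves the
    # threshold crossing (the marginal -40 pA bias makes LIF the most
    # step-sensitive model), with per-row balanced static weights
    return dict(
        neuron=NeuronParams.lif(time_unit="s"),
        weights=WeightConfig(N=max(16, 2000 // scale), p=0.1, G=0.04,
                             Q=10.0, seed=seed, per_row=True),
        synapse=_THETA_SYN,
        supervisor=supervisors.sinusoid(5.0),
        schedule=TrainSchedule(dt=5e-5, dt_rls=2.5e-3,
                               t_init=1.0 / scale, t_train=4.0 / scale,
                               t_test=5.0 / scale, seed=seed + 1,
                               time_unit="s"),
        lam_inv=0.0025)


def _build_fig2_izh_sine(seed, scale):
    return dict(
        neuron=NeuronParams.izhikevich(),
        weights=WeightConfig(N=max(16, 2000 // scale), p=0.1, G=5e3, Q=5e3,
                             seed=seed),
        synapse=_MS_SYN,
        supervisor=supervisors.sinusoid(0.005),
        schedule=TrainSchedule(dt=0.04, dt_rls=0.8, t_init=1000.0 / scale,
                               t_train=4000.0 / scale,
                               t_test=5000.0 / scale, seed=seed + 1),
        lam_inv=1.0)


def _build_fig2_lorenz(seed, scale):
    sup = supervisors.lorenz(duration=120.0 / scale, seed=seed + 3)
    return _theta_preset(seed, scale, sup, G=14.0, N=5000,
                         t_init=5.0, t_train=45.0, t_test=50.0)


def _build_lorenz_lif_scaled(seed, scale):
    """Desk-scale Lorenz substitute: 1000 LIF neurons (seconds time base,
    bias -39 = the Lorenz-example value, slow τ_d = 50 ms synapses for
    the memory the slow z-dynamics need)."""
    sup = supervisors.lorenz(duration=60.0, seed=seed + 3)
    return dict(
        neuron=NeuronParams.lif(I_bias=-39.0, time_unit="s"),
        weights=WeightConfig(N=max(16, 1000 // scale), p=0.1,
                             G=0.04, Q=10.0, seed=seed, per_row=True),
        synapse=SynapseParams(tau_r=2e-3, tau_d=50e-3),
        supervisor=sup,
        schedule=TrainSchedule(dt=5e-5, dt_rls=2.5e-3, t_init=2.0,
                               t_train=25.0, t_test=12.0,
                               seed=seed + 1, time_unit="s"),
        lam_inv=0.0025)


def _build_fig3_ode_to_joy(seed, scale):
    sup = supervisors.note_song(supervisors.ODE_TO_JOY, time_scale=1000.0)
    return dict(
        neuron=NeuronParams.izhikevich(),
        weights=WeightConfig(N=max(16, 5000 // scale), p=0.1, G=1e4, Q=4e3,
                             seed=seed),
        synapse=_MS_SYN,
        supervisor=sup,
        schedule=TrainSchedule(dt=0.04, dt_rls=4.0, t_init=1000.0,
                               t_train=900e3 / scale, t_test=1000e3 / scale,
                               seed=seed + 1),
        lam_inv=2.0)


def _build_ode_to_joy_scaled(seed, scale):
    """Desk-scale song substitute: 1000 Izhikevich neurons learn the first
    bar (T = 1 s) with a slower decay constant (τ_d = 50 ms)."""
    sup = supervisors.note_song(supervisors.ODE_TO_JOY_BAR1,
                                time_scale=1000.0)
    return dict(
        neuron=NeuronParams.izhikevich(),
        weights=WeightConfig(N=1000, p=0.1, G=1e4, Q=4e3, seed=seed),
        synapse=SynapseParams(tau_r=2.0, tau_d=50.0),
        supervisor=sup,
        schedule=TrainSchedule(dt=0.04, dt_rls=4.0, t_init=500.0,
                               t_train=25e3, t_test=10e3, seed=seed + 1),
        lam_inv=2.0)


def _build_songbird_synthetic(seed, scale):
    """Songbird-style circuit: a 500-component feedforward pulse chain
    (20 ms period half-waves, 5 s song) drives an RA-like Izhikevich
    network trained on a synthetic spectrogram stand-in."""
    K = 500 // scale
    chain = supervisors.pulse_chain(K, period=20.0)
    T_song = chain.T
    sup = supervisors.moving_blob(8, T=T_song)
    sup.label = "synthetic_spectrogram"
    N = max(16, 1000 // scale)
    rng = np.random.default_rng(seed + 2)
    w_in = rng.uniform(-8e3, 8e3, size=(N, K))
    return dict(
        neuron=NeuronParams.izhikevich(songbird=True),
        weights=WeightConfig(N=N, p=0.1, G=1.3e4, Q=1e3, seed=seed),
        synapse=_MS_SYN,
        supervisor=sup,
        schedule=TrainSchedule(dt=0.04, dt_rls=4.0, t_init=T_song,
                               t_train=50e3 / scale, t_test=50e3 / scale,
                               seed=seed + 1),
        lam_inv=2.0,
        input_signal=chain, w_in=w_in)


def _build_hdts_replay_synthetic(seed, scale):
    """Movie-replay circuit with an external HDTS: an 8-pulse HDTS with
    the standard 250 ms pulse width (4 Hz assembly rate) drives a replay
    network trained on a 64-pixel synthetic moving-blob movie of
    duration 2 s."""
    T = 2000.0
    sup = supervisors.moving_blob(8, T=T)
    chain = supervisors.hdts(supervisors.HDTSSpec(T=T, m=8))
    N = max(16, 1000 // scale)
    rng = np.random.default_rng(seed + 2)
    w_in = rng.uniform(-4e3, 4e3, size=(N, chain.m))
    return dict(
        neuron=NeuronParams.izhikevich(),
        weights=WeightConfig(N=N, p=0.1, G=5e3, Q=4e2, seed=seed),
        synapse=_MS_SYN,
        supervisor=sup,
        schedule=TrainSchedule(dt=0.04, dt_rls=4.0, t_init=T,
                               t_train=16 * T / scale, t_test=3 * T,
                               seed=seed + 1),
        lam_inv=2.0,
        input_signal=chain, w_in=w_in)


_BUILDERS: dict[str, Callable] = {
    "fig1_rate": _build_fig1_rate,
    "fig2_theta_sine": _build_fig2_theta_sine,
    "fig2_theta_sawtooth": _build_fig2_theta_sawtooth,
    "fig2_theta_vdp_harmonic": _build_fig2_theta_vdp_harmonic,
    "fig2_theta_vdp_relaxation": _build_fig2_theta_vdp_relaxation,
    "fig2_theta_product_of_sines": _build_fig2_theta_product_of_sines,
    "fig2_theta_product_of_sines_noise":
        _build_fig2_theta_product_of_sines_noise,
    "fig2_lif_sine": _build_fig2_lif_sine,
    "fig2_izh_sine": _build_fig2_izh_sine,
    "fig2_lorenz": _build_fig2_lorenz,
    "lorenz_lif_scaled": _build_lorenz_lif_scaled,
    "fig3_ode_to_joy": _build_fig3_ode_to_joy,
    "ode_to_joy_scaled": _build_ode_to_joy_scaled,
    "songbird_synthetic": _build_songbird_synthetic,
    "hdts_replay_synthetic": _build_hdts_replay_synthetic,
}

_SWEEPS = ("chaos_sweep_theta", "chaos_sweep_izhikevich",
           "convergence_lif", "convergence_rate")

PRESET_NAMES = tuple(_BUILDERS) + _SWEEPS


def get_preset(name: str, seed: int = 0, overrides: Optional[dict] = None):
    """Build the component bundle for a preset.

    ``name`` may carry a ``_small`` suffix (N and durations ÷ 4).
    Overrides replace top-level entries (e.g. ``schedule``) or, for dotted
    keys like ``"weights.G"``, a single field.
    """
    scale = 1
    base = name
    if name.endswith("_small"):
        base = name[: -len("_small")]
        scale = 4
    if base not in _BUILDERS:
        raise KeyError(f"unknown preset {name!r}; known: "
                       f"{sorted(PRESET_NAMES)}")
    cfg = _BUILDERS[base](seed, scale)
    cfg.setdefault("input_signal", None)
    cfg.setdefault("w_in", None)
    cfg["name"] = name
    for key, val in (overrides or {}).items():
        if "." in key:
            head, field = key.split(".", 1)
            if head not in cfg or not hasattr(cfg[head], field):
                raise KeyError(f"invalid override {key!r}")
            setattr(cfg[head], field, val)
        elif key in cfg:
            cfg[key] = val
        else:
            raise KeyError(f"invalid override {key!r}")
    return cfg


def _summarize(result, cfg) -> dict:
    test = result.phase_slice("test")
    summary = {
        "mean_rate_hz": result.mean_rate_hz,
        "max_unit_rate_hz": result.max_unit_rate_hz,
        "l2_test": result.errors["test"],
        "l2_train": result.errors["train"],
        "n_spikes": int(result.spike_ids.size),
    }
    try:
        summary["test_correlation"] = metrics.time_avg_correlation(
            result.xhat[test], result.x[test])
    except ValueError:
        summary["test_correlation"] = None
    return summary


def run_preset(name: str, overrides: Optional[dict] = None,
               seed: int = 0, outdir=None):
    """Execute a preset end to end; optionally write artifacts.

    Returns ``(result, summary)`` where ``result`` is a TrainResult for
    training presets or a sweep table for the chaos/convergence presets.
    Written artifacts: raster.txt, trace.csv, metrics.json, manifest.json.
    """
    if name in _SWEEPS or (name.endswith("_small")
                           and name[:-6] in _SWEEPS):
        return _run_sweep(name, seed, outdir)
    cfg = get_preset(name, seed=seed, overrides=overrides)
    kwargs = dict(lam_inv=cfg["lam_inv"])
    if cfg["input_signal"] is not None:
        result = train_with_input(cfg["neuron"], cfg["weights"],
                                  cfg["synapse"], cfg["supervisor"],
                                  cfg["schedule"], cfg["input_signal"],
                                  cfg["w_in"], **kwargs)
    else:
        result = train(cfg["neuron"], cfg["weights"], cfg["synapse"],
                       cfg["supervisor"], cfg["schedule"], **kwargs)
    summary = _summarize(result, cfg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_raster(outdir / "raster.txt", result.spike_times,
                        result.spike_ids)
        io.write_trace(outdir / "trace.csv", result.t, result.xhat,
                       result.x)
        io.write_json(outdir / "metrics.json", summary)
        io.write_manifest(outdir, name, _config_dict(cfg), seed)
    return result, summary


def _config_dict(cfg) -> dict:
    out = {"name": cfg["name"]}
    for key in ("neuron", "synapse", "schedule"):
        out[key] = dataclasses.asdict(cfg[key])
    w = cfg["weights"]
    out["weights"] = {"N": w.N, "p": w.p, "G": w.G, "Q": w.Q,
                      "seed": w.seed, "variance": w.variance}
    out["supervisor"] = {"label": cfg["supervisor"].label,
                         "m": cfg["supervisor"].m,
                         "T": cfg["supervisor"].T}
    out["lam_inv"] = cfg["lam_inv"]
    return out


def _run_sweep(name: str, seed: int, outdir):
    small = name.endswith("_small")
    base = name[:-6] if small else name
    if base == "chaos_sweep_theta":
        out = metrics.chaos_onset_sweep(
            "theta", G_grid=[0.005, 0.01, 0.02, 0.04, 0.08],
            trials=3, N=500 if small else 1000,
            duration=2.0 if small else 4.0, dt=1e-4,
            time_unit="s", seed=seed)
    elif base == "chaos_sweep_izhikevich":
        out = metrics.chaos_onset_sweep(
            "izhikevich", G_grid=[250.0, 500.0, 1e3, 2e3, 4e3],
            trials=3, N=250 if small else 500, duration=600.0, dt=0.04,
            time_unit="ms", seed=seed)
    elif base == "convergence_lif":
        out = metrics.convergence_experiment(
            "lif", N_list=[250, 500, 1000] if small
            else [250, 500, 1000, 2000], reps=3, seed=seed)
    elif base == "convergence_rate":
        out = metrics.convergence_experiment(
            "rate", N_list=[250, 500, 1000] if small
            else [250, 500, 1000, 2000, 4000], reps=3, seed=seed)
    else:
        raise KeyError(f"unknown sweep preset {name!r}")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in out.items() if k != "errors"}
        io.write_json(outdir / "metrics.json", serializable)
        io.write_manifest(outdir, name, {"name": name}, seed)
    return out, out


def make_convergence_runner(model: str, supervisor=None) -> Callable:
    """Return ``runner(N, seed) -> test-phase L2 error`` for the
    network-size convergence experiment (standard sinusoid settings)."""
    if model == "rate":
        # 8 s of training: a convergence-rate measurement needs the
        # training residual gone, otherwise it contaminates the
        # representation-error scaling at small N
        def runner(N, seed):
            sup = supervisor or supervisors.sinusoid(0.005)
            w = WeightConfig(N=N, p=0.1, G=1.0, Q=1.5, seed=seed,
                             variance="np", scale=0.1)
            sched = TrainSchedule(dt=0.5, dt_rls=2.0, t_init=500.0,
                                  t_train=8000.0, t_test=2000.0,
                                  seed=seed + 1)
            res = train(NeuronParams.rate(), w, _MS_SYN, sup, sched,
                        lam_inv=0.5)
            return res.errors["test"]
        return runner
    if model == "lif":
        def runner(N, seed):
            sup = supervisor or supervisors.sinusoid(5.0)
            w = WeightConfig(N=N, p=0.1, G=0.04, Q=10.0, seed=seed,
                             per_row=True)
            sched = TrainSchedule(dt=5e-5, dt_rls=2.5e-3, t_init=0.5,
                                  t_train=4.0, t_test=2.5,
                                  seed=seed + 1, time_unit="s")
            res = train(NeuronParams.lif(time_unit="s"), w, _THETA_SYN,
                        sup, sched, lam_inv=0.0025)
            return res.errors["test"]
        return runner
    raise ValueError(f"no convergence runner for model {model!r}")


def run_hdts_perturbation_suite(seed: int = 0,
                                train_reps: int = 16,
                                compressions=(4.0,),
                                lesion_fractions=(0.0, 0.2, 0.5),
                                test_reps: int = 3) -> dict:
    """Train the external-HDTS replay circuit once, then replay it under
    HDTS compression and under replay-network lesioning.

    Returns the time-averaged correlation between network output and the
    movie supervisor for the unperturbed network, for each compression
    factor (output compared against the correspondingly sped-up movie),
    and for each lesion fraction.  The decoders are frozen throughout the
    perturbed replays.
    """
    cfg = get_preset("hdts_replay_synthetic", seed=seed)
    T = cfg["supervisor"].T
    cfg["schedule"].t_train = train_reps * T
    cfg["schedule"].t_test = test_reps * T
    result = train_with_input(cfg["neuron"], cfg["weights"], cfg["synapse"],
                              cfg["supervisor"], cfg["schedule"],
                              cfg["input_signal"], cfg["w_in"],
                              lam_inv=cfg["lam_inv"])
    test = result.phase_slice("test")
    out = {"r_unperturbed": metrics.time_avg_correlation(
        result.xhat[test], result.x[test])}
    decoder = result.decoder

    def replay(weights, w_in, input_signal, target, duration):
        sim = rls.simulate(cfg["neuron"], weights, cfg["synapse"],
                           duration, cfg["schedule"].dt,
                           seed=cfg["schedule"].seed + 17,
                           time_unit=cfg["schedule"].time_unit,
                           chunk=cfg["schedule"].dt_rls,
                           decoder=decoder, supervisor=target,
                           input_signal=input_signal, w_in=w_in)
        sl = sim.t > 0.25 * duration  # discard startup transient
        return metrics.time_avg_correlation(sim.xhat[sl], sim.x[sl])

    out["r_compressed"] = {}
    for c in compressions:
        fast_hdts = perturb.transform_hdts(cfg["input_signal"],
                                           compression=c)
        fast_movie = perturb.transform_hdts(cfg["supervisor"],
                                            compression=c)
        out["r_compressed"][c] = replay(cfg["weights"], cfg["w_in"],
                                        fast_hdts, fast_movie,
                                        test_reps * T)
    out["r_lesioned"] = {}
    for frac in lesion_fractions:
        w2, d2, win2 = perturb.lesion_neurons(
            cfg["weights"], decoder, cfg["w_in"], fraction=frac,
            seed=seed + 101)
        sim = rls.simulate(cfg["neuron"], w2, cfg["synapse"],
                           test_reps * T, cfg["schedule"].dt,
                           seed=cfg["schedule"].seed + 17,
                           time_unit=cfg["schedule"].time_unit,
                           chunk=cfg["schedule"].dt_rls,
                           decoder=d2, supervisor=cfg["supervisor"],
                           input_signal=cfg["input_signal"], w_in=win2)
        sl = sim.t > 0.25 * test_reps * T
        out["r_lesioned"][frac] = metrics.time_avg_correlation(
            sim.xhat[sl], sim.x[sl])
    return out


def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0,
                 outdir="."):
    """Deterministic small files for tests and inspection."""
    params = params or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "supervisor_trace":
        sup = supervisors.sinusoid(params.get("freq", 5.0))
        t = np.linspace(0, params.get("T", 1.0), params.get("n", 201))
        table = supervisors.sample_to_table(sup, t)
        path = outdir / "supervisor_trace.csv"
        np.savetxt(path, table, delimiter=",")
        return path
    if kind == "toy_raster":
        rate = params.get("rate_hz", 10.0)
        T = params.get("T_s", 1.0)
        times = np.arange(1, int(rate * T) + 1) / rate * 1000.0
        path = outdir / "toy_raster.txt"
        io.write_raster(path, times, np.zeros(times.size, dtype=int))
        return path
    if kind == "weights_small":
        w = WeightConfig(N=params.get("N", 50), p=0.2, G=1.0, Q=1.0,
                         seed=seed)
        w.realize("lif", params.get("m", 1))
        path = outdir / "weights_small.npz"
        w.save(path)
        return path
    if kind == "movie_synthetic":
        sup = supervisors.moving_blob(params.get("n_side", 16),
                                      T=params.get("T", 1.0))
        t = np.linspace(0, sup.T, params.get("frames", 64), endpoint=False)
        table = supervisors.sample_to_table(sup, t)
        path = outdir / "movie_synthetic.csv"
        np.savetxt(path, table, delimiter=",", fmt="%.5f")
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")


def report(run_dir) -> Path:
    """Render a static markdown report from a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest in {run_dir}")
    manifest = io.read_json(manifest_path)
    lines = [f"# Run report: {manifest['preset']}", "",
             f"- seed: {manifest['seed']}",
             f"- config hash: {manifest['config_hash']}",
             f"- package version: {manifest['version']}", ""]
    metrics_path = run_dir / "metrics.json"
    if metrics_path.exists():
        lines.append("## Metrics\n")
        for key, val in sorted(io.read_json(metrics_path).items()):
            lines.append(f"- {key}: {val}")
        lines.append("")
    raster_path = run_dir / "raster.txt"
    if raster_path.exists():
        times, ids = io.read_raster(raster_path)
        lines.append(f"## Raster ({times.size} events; first 10)\n")
        for t, i in zip(times[:10], ids[:10]):
            lines.append(f"- t={t:.3f}  neuron={i}")
        lines.append("")
    trace_path = run_dir / "trace.csv"
    if trace_path.exists():
        with open(trace_path) as fh:
            head = [next(fh) for _ in range(min(6, sum(1 for _ in open(trace_path))))]
        lines.append("## Decoded-vs-target trace (head)\n")
        lines.append("```")
        lines.extend(s.rstrip() for s in head)
        lines.append("```")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
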