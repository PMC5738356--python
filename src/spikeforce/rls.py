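"""FORCE training: network approximant, error feedback and recursive least
squares (RLS) decoder updates.

The network output is the linear readout x̂(t) = Σ_j φ_j r_j(t) of the
filtered spike trains.  FORCE training clamps the output error from the
first moment: the approximant is fed back into every neuron as a current
Q η · x̂ at every integration step, while the decoders φ are updated every
Δt (``dt_rls``) of simulated time by RLS,

    e(t) = x̂(t) - x(t)                       (prior decoders)
    P(t) = P(t-Δt) - P r rᵀ P / (1 + rᵀ P r)
    φ(t) = φ(t-Δt) - P(t) r eᵀ

with φ(0) = 0 and P(0) = I_N λ⁻¹.  P estimates the regularized inverse
correlation matrix of r, so on any fixed sample sequence the
``denominator`` variant is algebraically identical to batch ridge
regression (Σ r rᵀ + λ I)⁻¹ Σ r xᵀ — the primary correctness oracle.  The
``plain`` variant applies the φ update with the pre-update gain P(t-Δt) r
(no 1 + rᵀPr denominator in the φ path); both are exposed because the two
published descriptions of the method differ on this point, and the
difference does not change the order of convergence.

A training run has three phases: an initialization phase with RLS off (the
network settles onto its chaotic attractor), a training phase with RLS
applied every ``dt_rls``, and a test phase with the decoders frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.linalg.blas as blas
import scipy.sparse as sp

from . import _kernels
from .neurons import (IntegrationInstabilityError, NeuronParams,
                      initial_state, rate_transfer)
from .supervisors import Supervisor
from .synapses import SynapseParams, WeightConfig

__all__ = [
    "DecoderState",
    "TrainSchedule",
    "TrainResult",
    "TrainingDivergenceError",
    "approximant",
    "rls_step",
    "train",
    "train_with_input",
    "simulate",
]


class TrainingDivergenceError(RuntimeError):
    """RLS conditioning collapse or runaway network activity."""


def approximant(phi: np.ndarray, r: np.ndarray) -> np.ndarray:
    """x̂ = φᵀ r (m-vector)."""
    phi = np.atleast_2d(phi.T).T  # promote (N,) -> (N, 1)
    if phi.shape[0] != r.shape[0]:
        raise ValueError(
            f"shape mismatch: phi {phi.shape} vs r {r.shape}")
    return phi.T @ r


@dataclass
class DecoderState:
    """Decoders φ (N×m), inverse-correlation estimate P (N×N), λ."""

    phi: np.ndarray
    P: np.ndarray
    lam_inv: float
    variant: str = "denominator"
    n_updates: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("denominator", "plain"):
            raise ValueError("variant must be 'denominator' or 'plain'")

    @classmethod
    def init(cls, N: int, m: int, lam_inv: float,
             variant: str = "denominator") -> "DecoderState":
        if lam_inv <= 0:
            raise ValueError("lam_inv must be positive")
        return cls(phi=np.zeros((N, m)), P=np.eye(N) * lam_inv,
                   lam_inv=lam_inv, variant=variant)


def rls_step(ds: DecoderState, r: np.ndarray, e: np.ndarray) -> DecoderState:
    """One rank-one RLS update (in place).

    ``e = x̂ - x`` uses the prior decoders.  The P update is the
    Sherman–Morrison rank-one formula; P stays exactly symmetric because
    the subtracted outer product c cᵀ is symmetric element for element.
    With e = 0 the decoders are untouched but P still absorbs the sample.
    """
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if e.shape[0] != ds.phi.shape[1]:
        raise ValueError(f"error dim {e.shape[0]} != output dim "
                         f"{ds.phi.shape[1]}")
    c = ds.P @ r
    denom = 1.0 + float(r @ c)
    if not np.isfinite(denom) or denom <= 0.0:
        raise TrainingDivergenceError(
            f"P-matrix conditioning collapse at update {ds.n_updates}"
            f" (denominator {denom!r})")
    N = c.shape[0]
    if N >= 1024 and ds.P.flags["C_CONTIGUOUS"]:
        # fused in-place rank-1 update: one pass over P instead of three
        # (the temporary-free path matters once P no longer fits in cache)
        blas.dger(-1.0 / denom, c, c, a=ds.P.T, overwrite_a=1)
    else:
        ds.P -= np.outer(c, c) / denom
    gain = c / denom if ds.variant == "denominator" else c
    ds.phi -= np.outer(gain, e)
    ds.n_updates += 1
    return ds


@dataclass
class TrainSchedule:
    """Integration step, RLS cadence and phase durations.

    All times share one unit (ms for LIF/Izhikevich presets, s for theta
    presets); ``time_unit`` records which, so that rates can be reported in
    Hz.  ``dt_rls`` must be an integer multiple of ``dt``.
    """

    dt: float
    dt_rls: float
    t_init: float
    t_train: float
    t_test: float
    seed: int = 0
    time_unit: str = "ms"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt_rls < self.dt:
            raise ValueError("dt_rls must be >= dt")
        n = self.dt_rls / self.dt
        if abs(n - round(n)) > 1e-6 * n:
            raise ValueError("dt_rls must be an integer multiple of dt")
        if min(self.t_init, self.t_train, self.t_test) < 0:
            raise ValueError("phase durations must be non-negative")
        if self.time_unit not in ("ms", "s"):
            raise ValueError("time_unit must be 'ms' or 's'")

    @property
    def steps_per_rls(self) -> int:
        return int(round(self.dt_rls / self.dt))

    @property
    def unit_to_seconds(self) -> float:
        return 1e-3 if self.time_unit == "ms" else 1.0


@dataclass
class TrainResult:
    """Raster, decoded trace, decoder history and summary metrics."""

    spike_times: np.ndarray       # event times, schedule units
    spike_ids: np.ndarray         # neuron indices
    t: np.ndarray                 # sample times of xhat (chunk boundaries)
    xhat: np.ndarray              # (n, m) decoded output
    x: np.ndarray                 # (n, m) target at the same times
    decoder: DecoderState
    phases: dict                  # name -> (t0, t1)
    errors: dict                  # per-phase time-averaged L2 error
    mean_rate_hz: dict            # per-phase network-mean firing rate
    max_unit_rate_hz: float       # max over units of time-averaged rate
    phi_norms: np.ndarray         # ||φ||_F at each chunk boundary
    phi_snapshots: dict           # phase-boundary decoder copies
    time_unit: str = "ms"
    unit_rates_hz: Optional[np.ndarray] = None
    unit_rates_by_phase: Optional[dict] = None

    def phase_slice(self, name: str) -> np.ndarray:
        t0, t1 = self.phases[name]
        return (self.t > t0) & (self.t <= t1)


def _phase_l2(xhat, x, mask):
    if mask.sum() < 2:
        return float("nan")
    d = xhat[mask] - x[mask]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def train(neuron: NeuronParams, weights: WeightConfig,
          synapse: SynapseParams, supervisor: Supervisor,
          schedule: TrainSchedule, decoder: Optional[DecoderState] = None,
          lam_inv: float = 1.0, variant: str = "denominator",
          input_signal: Optional[Supervisor] = None,
          w_in: Optional[np.ndarray] = None,
          record_raster: bool = True,
          runaway_rate_hz: float = 400.0,
          delete_spike: Optional[tuple] = None,
          rls_active: bool = True) -> TrainResult:
    """Run the full init/train/test FORCE schedule and return a TrainResult.

    The feedback current Q η · x̂ uses the current approximant at every
    integration step; RLS touches the decoders only every ``dt_rls``.
    ``delete_spike = (neuron, step)`` suppresses transmission of that one
    spike (chaos diagnostic).  Aborts with :class:`TrainingDivergenceError`
    if the running network-mean rate exceeds ``runaway_rate_hz``.
    """
    if neuron.model == "rate":
        return _train_rate(neuron, weights, synapse, supervisor, schedule,
                           decoder, lam_inv, variant, record_raster)

    m = supervisor.m
    weights.realize(neuron.model, m)
    N = weights.N
    rng = np.random.default_rng(schedule.seed)
    state = initial_state(neuron, N, rng)
    if decoder is None:
        decoder = DecoderState.init(N, m, lam_inv, variant)
    if decoder.phi.shape != (N, m):
        raise ValueError("decoder shape does not match network/supervisor")

    dt = schedule.dt
    n_sub = schedule.steps_per_rls
    single = synapse.is_single
    if single:
        e_r = e_d = np.exp(-dt / synapse.tau_s)
        inv_jump = 1.0 / synapse.tau_s
        cpl = 0.0
    else:
        tau_r, tau_d = synapse.tau_r, synapse.tau_d
        e_r = np.exp(-dt / tau_r)
        e_d = np.exp(-dt / tau_d)
        inv_jump = 1.0 / (tau_r * tau_d)
        if abs(tau_d - tau_r) > 1e-12 * tau_d:
            cpl = tau_r * tau_d * (e_d - e_r) / (tau_d - tau_r)
        else:
            cpl = dt * e_d

    w0 = weights.omega0.tocsc()
    # presynaptic column access: kernel indexes CSC columns by spiking neuron
    indptr = w0.indptr.astype(np.int64)
    indices = w0.indices.astype(np.int64)
    wdata = (weights.G * w0.data * inv_jump).astype(np.float64)
    etaQ = np.ascontiguousarray(weights.Q * weights.eta, dtype=np.float64)

    model_id = {"theta": _kernels.MODEL_THETA, "lif": _kernels.MODEL_LIF,
                "izhikevich": _kernels.MODEL_IZH}[neuron.model]
    v = state.v.astype(np.float64)
    u = state.u.astype(np.float64)
    refrac = state.refrac.astype(np.float64)
    Ips = np.zeros(N)
    Hps = np.zeros(N)
    r = np.zeros(N)
    hr = np.zeros(N)
    y1 = np.zeros(m)
    y2 = np.zeros(m)
    no_ext = np.zeros((0, 0))
    if input_signal is not None and w_in is None:
        raise ValueError("input_signal requires w_in")
    if w_in is not None and input_signal is not None \
            and w_in.shape != (N, input_signal.m):
        raise ValueError("w_in must be N x K for a K-dim input signal")

    del_neuron, del_step = (-1, -1) if delete_spike is None else delete_spike

    cap = max(N * n_sub, 1024)
    spk_step_buf = np.empty(cap, dtype=np.int64)
    spk_id_buf = np.empty(cap, dtype=np.int64)
    all_steps: list = []
    all_ids: list = []
    spike_counts = np.zeros(N, dtype=np.int64)
    phase_unit_counts = {nm: np.zeros(N, dtype=np.int64)
                         for nm in ("init", "train", "test")}

    phases = []
    t_cursor = 0.0
    for name, dur, learn in (("init", schedule.t_init, False),
                             ("train", schedule.t_train, rls_active),
                             ("test", schedule.t_test, False)):
        n_chunks = int(round(dur / schedule.dt_rls))
        phases.append((name, n_chunks, learn, t_cursor))
        t_cursor += n_chunks * schedule.dt_rls
    phase_bounds = {nm: (t0, t0 + nc * schedule.dt_rls)
                    for nm, nc, _, t0 in phases}
    phase_spikes = {nm: 0 for nm, *_ in phases}

    ts, xhats, xs, phi_norms = [], [], [], []
    phi_snapshots = {}
    params = neuron
    step0 = 0
    # runaway check over a ~100-chunk rolling window
    win = 100
    recent = np.zeros(win, dtype=np.int64)
    to_hz = 1.0 / schedule.unit_to_seconds

    sym_every = 100 if N > 1000 else 1
    for name, n_chunks, learn, t0_phase in phases:
        phi_snapshots[name] = decoder.phi.copy()
        for chunk in range(n_chunks):
            t_start = step0 * dt
            if input_signal is not None:
                t_steps = t_start + dt * np.arange(1, n_sub + 1)
                U = np.atleast_2d(input_signal(t_steps))      # (n_sub, K)
                act = np.flatnonzero(np.abs(U).max(axis=0) > 0)
                if act.size:
                    Eext = np.ascontiguousarray(
                        U[:, act] @ w_in[:, act].T)
                else:
                    Eext = np.zeros((n_sub, N))
            else:
                Eext = no_ext
            nsp = _kernels.run_chunk(
                model_id, n_sub, step0, dt,
                v, u, refrac, Ips, Hps, r, hr, y1, y2,
                indptr, indices, wdata, etaQ, decoder.phi,
                float(params.I_bias), Eext,
                single, e_r, e_d, cpl, inv_jump,
                params.C, params.k, params.v_r, params.v_t, params.v_reset,
                params.v_peak, params.a, params.b, params.d,
                params.tau_m, params.tau_ref,
                del_neuron, del_step,
                spk_step_buf, spk_id_buf)
            step0 += n_sub
            t_now = step0 * dt
            if nsp:
                ids = spk_id_buf[:nsp]
                np.add.at(spike_counts, ids, 1)
                np.add.at(phase_unit_counts[name], ids, 1)
                phase_spikes[name] += nsp
                if record_raster:
                    all_steps.append(spk_step_buf[:nsp].copy())
                    all_ids.append(ids.copy())
            recent[(step0 // n_sub) % win] = nsp
            if (step0 // n_sub) % win == win - 1:
                window_rate = recent.sum() / (N * win * schedule.dt_rls) * to_hz
                if window_rate > runaway_rate_hz:
                    raise TrainingDivergenceError(
                        f"network-mean rate {window_rate:.1f} Hz exceeds "
                        f"runaway bound {runaway_rate_hz} Hz at t={t_now:g}")
                if not np.all(np.isfinite(v)):
                    idx = int(np.flatnonzero(~np.isfinite(v))[0])
                    raise IntegrationInstabilityError(
                        f"non-finite state for neuron {idx} at t={t_now:g}")
            x_t = np.atleast_1d(supervisor(t_now)).astype(float)
            if learn:
                e = decoder.phi.T @ r - x_t
                rls_step(decoder, r, e)
                if decoder.n_updates % sym_every == 0:
                    decoder.P = 0.5 * (decoder.P + decoder.P.T)
            # refresh tracked projections (also kills fp drift)
            y1[:] = decoder.phi.T @ r
            y2[:] = decoder.phi.T @ hr
            ts.append(t_now)
            xhats.append(y1.copy())
            xs.append(x_t)
            phi_norms.append(float(np.linalg.norm(decoder.phi)))
    phi_snapshots["final"] = decoder.phi.copy()

    spike_times = (np.concatenate(all_steps) * dt if all_steps
                   else np.empty(0))
    spike_ids = (np.concatenate(all_ids) if all_ids
                 else np.empty(0, dtype=np.int64))
    t_arr = np.asarray(ts)
    xhat_arr = np.asarray(xhats)
    x_arr = np.asarray(xs)
    errors = {}
    mean_rate = {}
    for nm, (p0, p1) in phase_bounds.items():
        mask = (t_arr > p0) & (t_arr <= p1)
        errors[nm] = _phase_l2(xhat_arr, x_arr, mask)
        dur = p1 - p0
        mean_rate[nm] = (phase_spikes[nm] / (N * dur) * to_hz
                         if dur > 0 else 0.0)
    total_dur = t_cursor if t_cursor > 0 else 1.0
    unit_rates = spike_counts / total_dur * to_hz
    rates_by_phase = {}
    for nm, (p0, p1) in phase_bounds.items():
        dur = p1 - p0
        rates_by_phase[nm] = (phase_unit_counts[nm] / dur * to_hz
                              if dur > 0 else np.zeros(N))
    return TrainResult(
        spike_times=spike_times, spike_ids=spike_ids,
        t=t_arr, xhat=xhat_arr, x=x_arr, decoder=decoder,
        phases=phase_bounds, errors=errors, mean_rate_hz=mean_rate,
        max_unit_rate_hz=float(unit_rates.max()) if N else 0.0,
        phi_norms=np.asarray(phi_norms), phi_snapshots=phi_snapshots,
        time_unit=schedule.time_unit, unit_rates_hz=unit_rates,
        unit_rates_by_phase=rates_by_phase)


def train_with_input(neuron, weights, synapse, supervisor, schedule,
                     input_signal: Supervisor, w_in: np.ndarray,
                     **kwargs) -> TrainResult:
    """FORCE training with an additional feedforward current W_in·input(t).

    Used for the external-HDTS and pulse-chain (songbird-style) circuits.
    With ``input_signal`` identically zero this reduces exactly to
    :func:`train` at the same seed.
    """
    return train(neuron, weights, synapse, supervisor, schedule,
                 input_signal=input_signal, w_in=w_in, **kwargs)


def simulate(neuron, weights, synapse, duration, dt, seed=0,
             time_unit="ms", chunk: Optional[float] = None,
             delete_spike=None, supervisor: Optional[Supervisor] = None,
             decoder: Optional[DecoderState] = None,
             input_signal=None, w_in=None,
             runaway_rate_hz: float = 1e9) -> TrainResult:
    """Free-running simulation (no learning).

    With ``decoder`` given, its frozen φ closes the feedback loop; otherwise
    φ = 0 and the network runs on its static weights alone.
    """
    if supervisor is not None:
        sup = supervisor
    else:
        m = decoder.phi.shape[1] if decoder is not None else 1
        sup = Supervisor.zero(m=m)
    chunk = chunk if chunk is not None else max(dt, duration / 1000.0)
    n = max(1, round(chunk / dt))
    sched = TrainSchedule(dt=dt, dt_rls=n * dt, t_init=duration,
                          t_train=0.0, t_test=0.0, seed=seed,
                          time_unit=time_unit)
    return train(neuron, weights, synapse, sup, sched, decoder=decoder,
                 input_signal=input_signal, w_in=w_in,
                 delete_spike=delete_spike, rls_active=False,
                 runaway_rate_hz=runaway_rate_hz)


# ---------------------------------------------------------------------------
# rate-network baseline
# ---------------------------------------------------------------------------

def _train_rate(neuron, weights, synapse, supervisor, schedule, decoder,
                lam_inv, variant, record_raster) -> TrainResult:
    """FORCE training of the rate baseline (dense numpy loop).

    The unit "filtered output" is the instantaneous rate r = F √s; the
    recurrent drive G ω⁰ r + Q η x̂ enters through the first-order current
    dynamics.  Everything else (RLS cadence, phases) matches the spiking
    driver.
    """
    m = supervisor.m
    weights.realize("rate", m)
    N = weights.N
    rng = np.random.default_rng(schedule.seed)
    s = initial_state(neuron, N, rng).v
    if decoder is None:
        decoder = DecoderState.init(N, m, lam_inv, variant)
    dt = schedule.dt
    n_sub = schedule.steps_per_rls
    W = (weights.G * weights.omega0).tocsr()
    etaQ = weights.Q * weights.eta
    F, tau_s = neuron.F, neuron.tau_s
    to_hz = 1.0 / schedule.unit_to_seconds

    phases = [("init", int(round(schedule.t_init / schedule.dt_rls)), False),
              ("train", int(round(schedule.t_train / schedule.dt_rls)), True),
              ("test", int(round(schedule.t_test / schedule.dt_rls)), False)]
    t0 = 0.0
    phase_bounds = {}
    for nm, nc, _ in phases:
        phase_bounds[nm] = (t0, t0 + nc * schedule.dt_rls)
        t0 = phase_bounds[nm][1]

    ts, xhats, xs, phi_norms = [], [], [], []
    phi_snapshots = {}
    rate_sum = np.zeros(N)
    n_samples = 0
    phase_rate = {nm: [0.0, 0] for nm, *_ in phases}
    phase_unit_sum = {nm: np.zeros(N) for nm, *_ in phases}
    step = 0
    r = rate_transfer(s, F)
    for nm, n_chunks, learn in phases:
        phi_snapshots[nm] = decoder.phi.copy()
        for _ in range(n_chunks):
            for _ in range(n_sub):
                xhat = decoder.phi.T @ r
                drive = W @ r + etaQ @ xhat
                s = s + dt * (drive - s) / tau_s
                r = rate_transfer(s, F)
                step += 1
                rate_sum += r
                phase_unit_sum[nm] += r
                phase_rate[nm][0] += r.mean()
                phase_rate[nm][1] += 1
                n_samples += 1
            if not np.all(np.isfinite(s)):
                idx = int(np.flatnonzero(~np.isfinite(s))[0])
                raise IntegrationInstabilityError(
                    f"non-finite rate-unit current for unit {idx} at "
                    f"t={step * dt:g}")
            t_now = step * dt
            x_t = np.atleast_1d(supervisor(t_now)).astype(float)
            if learn:
                e = decoder.phi.T @ r - x_t
                rls_step(decoder, r, e)
                if decoder.n_updates % 100 == 0:
                    decoder.P = 0.5 * (decoder.P + decoder.P.T)
            ts.append(t_now)
            xhats.append(decoder.phi.T @ r)
            xs.append(x_t)
            phi_norms.append(float(np.linalg.norm(decoder.phi)))
    phi_snapshots["final"] = decoder.phi.copy()

    t_arr = np.asarray(ts)
    xhat_arr = np.asarray(xhats)
    x_arr = np.asarray(xs)
    errors = {}
    mean_rate = {}
    for nm, (p0, p1) in phase_bounds.items():
        mask = (t_arr > p0) & (t_arr <= p1)
        errors[nm] = _phase_l2(xhat_arr, x_arr, mask)
        tot, cnt = phase_rate[nm]
        mean_rate[nm] = tot / cnt if cnt else 0.0
    unit_rates = rate_sum / max(n_samples, 1)
    rates_by_phase = {nm: phase_unit_sum[nm] / max(phase_rate[nm][1], 1)
                      for nm, *_ in phases}
    return TrainResult(
        spike_times=np.empty(0), spike_ids=np.empty(0, dtype=np.int64),
        t=t_arr, xhat=xhat_arr, x=x_arr, decoder=decoder,
        phases=phase_bounds, errors=errors, mean_rate_hz=mean_rate,
        max_unit_rate_hz=float(unit_rates.max()),
        phi_norms=np.asarray(phi_norms), phi_snapshots=phi_snapshots,
        time_unit=schedule.time_unit, unit_rates_hz=unit_rates,
        unit_rates_by_phase=rates_by_phase)
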