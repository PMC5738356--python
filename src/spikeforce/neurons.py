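"""Integrate-and-fire neuron models and the rate-unit baseline.

Three spiking models are supported, all advanced by explicit forward Euler:

* **theta** — phase model on the circle, equivalent to the quadratic
  integrate-and-fire neuron.  ``dθ/dt = (1 - cos θ) + π²(1 + cos θ) I``.
  A spike is emitted when θ crosses π from below, after which 2π is
  subtracted.  For constant suprathreshold drive the firing rate is √I per
  unit time (e.g. I = 0.04 → 0.2 spikes per unit time).  The equation is
  dimensionless: the caller chooses the unit of time (the network presets
  in :mod:`spikeforce.experiments` use seconds so that rates are in Hz).
* **lif** — leaky integrate-and-fire with an absolute refractory period,
  ``τ_m dv/dt = -v + I`` (unit resistance absorbed into I).  Spike when
  v ≥ v_t, then v → v_reset and the neuron is clamped there for τ_ref.
* **izhikevich** — quadratic model with a slow adaptation current u,
  ``C dv/dt = k (v - v_r)(v - v_t) - u + I``,
  ``du/dt = a (b (v - v_r) - u)``; spike when v ≥ v_peak, then v → v_reset
  and u → u + d.

The **rate** baseline uses the type-I normal-form transfer r = F √s (s ≥ 0,
else 0) with first-order current dynamics τ_s ds/dt = -s + drive.

Thresholds are detected *after* the Euler update; resets are applied before
the next step and spike times are recorded at the end of the step in which
the crossing occurred.  These numpy steppers are the reference semantics;
:mod:`spikeforce._kernels` implements the identical update compiled with
numba for whole-network training runs, and a test asserts their equivalence
step for step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkState",
    "IntegrationInstabilityError",
    "step_theta",
    "step_lif",
    "step_izhikevich",
    "rate_transfer",
    "step_rate_network",
    "initial_state",
]

_TWO_PI = 2.0 * np.pi


class IntegrationInstabilityError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


@dataclass
class NeuronParams:
    """Parameter set for one neuron model.

    Defaults (via the class methods below) are the paper-standard values for
    each model.  Units: time in ms for LIF/Izhikevich (potentials mV,
    currents pA, C in μF, k in nS/mV, b in nS, d in pA); the theta model is
    dimensionless and the rate model uses F (rate scale, Hz) and τ_s.
    """

    model: str
    C: float = 250.0
    v_r: float = -60.0
    v_t: float = -20.0
    v_reset: float = -65.0
    v_peak: float = 30.0
    a: float = 0.01
    b: float = 0.0
    d: float = 200.0
    k: float = 2.5
    tau_m: float = 10.0
    tau_ref: float = 2.0
    I_bias: float = 0.0
    F: float = 10.0
    tau_s: float = 10.0

    def __post_init__(self) -> None:
        if self.model not in ("theta", "lif", "izhikevich", "rate"):
            raise ValueError(f"unknown neuron model {self.model!r}")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.model in ("lif", "izhikevich"):
            if not (self.v_reset < self.v_t <= self.v_peak):
                raise ValueError("require v_reset < v_t <= v_peak")

    # -- Table-standard parameter sets ------------------------------------
    @classmethod
    def theta(cls, I_bias: float = 0.0) -> "NeuronParams":
        """Theta model: bias at rheobase (0) unless stated otherwise."""
        return cls(model="theta", I_bias=I_bias, v_peak=np.pi, v_reset=-np.pi,
                   v_t=0.0, v_r=-np.pi)

    @classmethod
    def lif(cls, I_bias: float = -40.0,
            time_unit: str = "ms") -> "NeuronParams":
        """LIF: τ_m=10 ms, τ_ref=2 ms, v_reset=-65, v_t=-40, bias -40
        (-39 for the Lorenz example).  ``time_unit='s'`` expresses the
        time constants in seconds (0.01/0.002) for seconds-based runs."""
        scale = 1e-3 if time_unit == "s" else 1.0
        return cls(model="lif", tau_m=10.0 * scale, tau_ref=2.0 * scale,
                   v_reset=-65.0, v_t=-40.0, v_peak=-40.0, v_r=-65.0,
                   I_bias=I_bias)

    @classmethod
    def izhikevich(cls, songbird: bool = False) -> "NeuronParams":
        """Izhikevich: C=250 μF, v_r=-60, v_t=-20, b=0 nS, v_peak=30,
        v_reset=-65, a=0.01/ms, d=200 pA, k=2.5 nS/mV, bias 1000 pA
        (at rheobase: k(v_t-v_r)²/4 = 1000 pA).  The songbird variant uses
        v_t=-40, a=0.002, d=100."""
        if songbird:
            return cls(model="izhikevich", v_t=-40.0, a=0.002, d=100.0,
                       I_bias=1000.0)
        return cls(model="izhikevich", I_bias=1000.0)

    @classmethod
    def rate(cls, F: float = 10.0, tau_s: float = 10.0) -> "NeuronParams":
        return cls(model="rate", F=F, tau_s=tau_s)


@dataclass
class NetworkState:
    """Per-neuron dynamical variables.

    ``v`` holds the membrane potential (mV) or, for the theta model, the
    phase θ wrapped to (-π, π].  ``u`` is the Izhikevich adaptation current
    (pA); ``refrac`` the remaining LIF refractory time.  ``t`` is the
    current simulation time.
    """

    v: np.ndarray
    u: np.ndarray
    refrac: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.v.copy(), self.u.copy(), self.refrac.copy(),
                            self.t)


def initial_state(params: NeuronParams, N: int,
                  rng: np.random.Generator) -> NetworkState:
    """Seedable desynchronized initial condition.

    Phases uniform in (-π, π] for the theta model; membrane potentials
    uniform in [v_reset, 30 mV] for LIF/Izhikevich, so that the fraction of
    initially suprathreshold neurons fires an igniting burst (with bias at
    rheobase the recurrent activity would otherwise never start); u = 0, no
    refractory carry-over.
    """
    if params.model == "theta":
        v = rng.uniform(-np.pi, np.pi, size=N)
    elif params.model == "rate":
        v = rng.uniform(0.0, 1.0, size=N)  # interpreted as current s
    else:
        v = rng.uniform(params.v_reset, 30.0, size=N)
    return NetworkState(v=v, u=np.zeros(N), refrac=np.zeros(N), t=0.0)


def _check_finite(x: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(x))[0])
        raise IntegrationInstabilityError(
            f"non-finite state for neuron {idx} at t={t!r}")


def step_theta(state: NetworkState, I: np.ndarray, dt: float,
               params: Optional[NeuronParams] = None):
    """One Euler step of the theta model.  Returns (state, spike flags)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    th = state.v
    th_new = th + dt * ((1.0 - np.cos(th)) + np.pi ** 2 * (1.0 + np.cos(th)) * I)
    spikes = th_new >= np.pi
    th_new = np.where(spikes, th_new - _TWO_PI, th_new)
    # guard wraps for pathologically large steps (no extra spike counted)
    th_new = np.where(th_new >= np.pi,
                      np.mod(th_new + np.pi, _TWO_PI) - np.pi, th_new)
    th_new = np.where(th_new < -np.pi,
                      np.mod(th_new + np.pi, _TWO_PI) - np.pi, th_new)
    _check_finite(th_new, state.t + dt)
    return NetworkState(th_new, state.u, state.refrac, state.t + dt), spikes


def step_lif(state: NetworkState, I: np.ndarray, dt: float,
             params: NeuronParams):
    """One Euler step of the LIF model with absolute refractoriness."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    refractory = state.refrac > 0
    v = np.where(refractory, params.v_reset,
                 state.v + dt * (-state.v + I) / params.tau_m)
    refrac = np.where(refractory, state.refrac - dt, 0.0)
    spikes = v >= params.v_t
    v = np.where(spikes, params.v_reset, v)
    refrac = np.where(spikes, params.tau_ref, refrac)
    _check_finite(v, state.t + dt)
    return NetworkState(v, state.u, refrac, state.t + dt), spikes


def step_izhikevich(state: NetworkState, I: np.ndarray, dt: float,
                    params: NeuronParams):
    """One Euler step of the Izhikevich model with adaptation."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    v_new = v + dt * (params.k * (v - params.v_r) * (v - params.v_t)
                      - u + I) / params.C
    u_new = u + dt * params.a * (params.b * (v - params.v_r) - u)
    spikes = v_new >= params.v_peak
    v_new = np.where(spikes, params.v_reset, v_new)
    u_new = np.where(spikes, u_new + params.d, u_new)
    _check_finite(v_new, state.t + dt)
    return NetworkState(v_new, u_new, state.refrac, state.t + dt), spikes


def rate_transfer(s: np.ndarray, F: float) -> np.ndarray:
    """Type-I normal-form rate: F·√s for s ≥ 0, else 0 (element-wise)."""
    s = np.asarray(s, dtype=float)
    return F * np.sqrt(np.maximum(s, 0.0))


def step_rate_network(s: np.ndarray, drive: np.ndarray, dt: float,
                      tau_s: float) -> np.ndarray:
    """Euler step of τ_s ds/dt = -s + drive.

    ``drive`` is the full recurrent-plus-feedback input G ω⁰ r + Q η x̂,
    assembled by the caller.
    """
    if dt <= 0 or tau_s <= 0:
        raise ValueError("dt and tau_s must be positive")
    s_new = s + dt * (drive - s) / tau_s
    if not np.all(np.isfinite(s_new)):
        idx = int(np.flatnonzero(~np.isfinite(s_new))[0])
        raise IntegrationInstabilityError(
            f"non-finite rate-unit current for unit {idx}")
    return s_new
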