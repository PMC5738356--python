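"""Teaching-signal generators.

Every supervisor is a deterministic function of time with a declared output
dimension ``m`` and period/duration ``T``: simple oscillators (sinusoid,
sawtooth, product of sinusoids, Van der Pol), the chaotic Lorenz system, a
note-pulse song, high-dimensional temporal signals (HDTS), feedforward
pulse chains, and a synthetic "moving blob" pixel movie standing in for
natural high-dimensional signals.

Frequencies are in cycles per *time unit* of the run that consumes the
supervisor: pass 5 for 5 Hz in a seconds-based run, 0.005 in an ms-based
run.

An HDTS discretizes an interval [0, T] into m subintervals
I_n = [T(n-1)/m, T n/m] and places one pulse per subinterval, centered at
T(2n-1)/(2m) — either a Gaussian bump of width σ or the piecewise function
|sin(mπt/T)| restricted to I_n.  Driving a network with an HDTS organizes
the neurons into sequentially active assemblies, which is what makes long
sequences learnable and replay manipulable (compression, reversal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Supervisor",
    "HDTSSpec",
    "sinusoid",
    "sawtooth",
    "product_of_sines",
    "van_der_pol",
    "lorenz",
    "lorenz_rhs",
    "note_song",
    "ODE_TO_JOY",
    "ODE_TO_JOY_BAR1",
    "hdts",
    "pulse_chain",
    "moving_blob",
    "stack",
    "sample_to_table",
]


@dataclass
class Supervisor:
    """Time-indexed m-dimensional target x(t).

    ``fn`` maps an array of times (n,) to outputs (n, m); scalar calls
    return an (m,) vector.  ``T`` is the period for periodic supervisors,
    otherwise the natural duration.
    """

    m: int
    T: float
    fn: Callable[[np.ndarray], np.ndarray]
    label: str = ""
    periodic: bool = True

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.asarray(self.fn(t_arr), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    @classmethod
    def zero(cls, m: int = 1, T: float = 1.0) -> "Supervisor":
        return cls(m=m, T=T, fn=lambda t: np.zeros((t.size, m)),
                   label="zero")


def sinusoid(freq: float, amplitude: float = 1.0) -> Supervisor:
    """amplitude·sin(2π f t); freq in cycles per time unit."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    return Supervisor(
        m=1, T=1.0 / freq,
        fn=lambda t: amplitude * np.sin(2 * np.pi * freq * t),
        label=f"sinusoid_{freq}")


def sawtooth(freq: float) -> Supervisor:
    """Rising ramp from -1 to 1, discontinuity at the period end."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    return Supervisor(
        m=1, T=1.0 / freq,
        fn=lambda t: 2.0 * np.mod(t * freq, 1.0) - 1.0,
        label=f"sawtooth_{freq}")


def product_of_sines(f1: float = 4.0, f2: float = 6.0,
                     noise_sd: float = 0.0,
                     seed: int = 0) -> Supervisor:
    """sin(2π f1 t)·sin(2π f2 t), optionally with fresh additive Gaussian
    noise per evaluation (seedable; default frequencies give period 0.5)."""
    rng = np.random.default_rng(seed)
    period = 1.0 / np.gcd(int(round(f1 * 2)), int(round(f2 * 2))) * 2.0 \
        if float(f1).is_integer() and float(f2).is_integer() else 1.0 / f1

    def fn(t):
        clean = np.sin(2 * np.pi * f1 * t) * np.sin(2 * np.pi * f2 * t)
        if noise_sd > 0:
            clean = clean + rng.normal(0.0, noise_sd, size=t.shape)
        return clean

    return Supervisor(m=1, T=period, fn=fn,
                      label=f"product_of_sines_{f1}x{f2}",
                      periodic=noise_sd == 0)


def _rk4(rhs, y0, h, n_steps):
    y = np.asarray(y0, dtype=float)
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    for i in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    return out


def van_der_pol(mu: float, speed: float = 20.0,
                raw: bool = False) -> Supervisor:
    """Van der Pol oscillator ẍ = μ(1 - x²)ẋ - x as a 2-dim supervisor.

    Integrated with fixed-step RK4, rescaled so the limit cycle lies within
    [-1, 1]² (unless ``raw``) and sped up in time by ``speed``.  μ = 0.3
    gives the near-harmonic regime, μ = 5 the relaxation regime.  For small
    μ the unscaled limit-cycle amplitude approaches the classical value 2.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    h = 0.001
    burn = _rk4(lambda y: np.array([y[1], mu * (1 - y[0] ** 2) * y[1] - y[0]]),
                [2.0, 0.0], h, int(60 / h))[-1]
    # one full period: detect two successive upward zero crossings of x
    traj = _rk4(lambda y: np.array([y[1], mu * (1 - y[0] ** 2) * y[1] - y[0]]),
                burn, h, int(40 / h))
    x = traj[:, 0]
    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if up.size < 2:
        raise RuntimeError("Van der Pol integration failed to find a cycle")
    i0, i1 = up[0] + 1, up[-1] + 1
    n_cyc = up.size - 1
    period = (i1 - i0) * h / n_cyc
    cycle = traj[i0:i0 + int(round(period / h)) + 1]
    scale = np.abs(cycle).max(axis=0)
    tt = np.arange(cycle.shape[0]) * h

    def fn(t):
        tau = np.mod(t * speed, period)
        out = np.column_stack([np.interp(tau, tt, cycle[:, 0]),
                               np.interp(tau, tt, cycle[:, 1])])
        return out if raw else out / scale

    sup = Supervisor(m=2, T=period / speed, fn=fn,
                     label=f"van_der_pol_mu{mu}")
    sup.raw_amplitude = float(scale[0])
    return sup


def lorenz_rhs(y: np.ndarray, rho: float = 28.0, sigma: float = 10.0,
               B: float = 8.0 / 3.0) -> np.ndarray:
    """ẋ = σ(y-x), ẏ = x(ρ-z) - y, ż = xy - Bz."""
    return np.array([sigma * (y[1] - y[0]),
                     y[0] * (rho - y[2]) - y[1],
                     y[0] * y[1] - B * y[2]])


def lorenz(rho: float = 28.0, sigma: float = 10.0, B: float = 8.0 / 3.0,
           duration: float = 100.0, normalize: bool = True,
           seed: int = 0, speed: float = 1.0) -> Supervisor:
    """Chaotic Lorenz trajectory after a burn-in onto the attractor.

    Components are normalized (zero mean, max-|value| 1 over the stored
    trajectory) by default so the feedback term sees O(1) signals;
    ``normalize=False`` returns raw coordinates.
    """
    if min(rho, sigma, B) <= 0:
        raise ValueError("parameters must be positive")
    h = 0.002
    rng = np.random.default_rng(seed)
    y0 = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
    rhs = lambda y: lorenz_rhs(y, rho, sigma, B)
    burn = _rk4(rhs, y0, h, int(30 / h))[-1]
    traj = _rk4(rhs, burn, h, int(duration * speed / h))
    offset = traj.mean(axis=0)
    scale = np.abs(traj - offset).max(axis=0)
    tt = np.arange(traj.shape[0]) * h

    def fn(t):
        tau = np.clip(t * speed, 0.0, tt[-1])
        out = np.column_stack([np.interp(tau, tt, traj[:, i])
                               for i in range(3)])
        if normalize:
            out = (out - offset) / scale
        return out

    sup = Supervisor(m=3, T=duration, fn=fn, label="lorenz", periodic=False)
    sup.raw_trajectory = traj
    return sup


_NOTE_INDEX = {"C": 0, "D": 1, "E": 2, "F": 3, "G": 4}

#: first bar of Ode to Joy: four quarter notes (1 s at 2 Hz pulses)
ODE_TO_JOY_BAR1 = [("E", "quarter"), ("E", "quarter"), ("F", "quarter"),
                   ("G", "quarter")]

#: the 4-bar Ode to Joy phrase, total duration 4 s
ODE_TO_JOY = ODE_TO_JOY_BAR1 + [
    ("G", "quarter"), ("F", "quarter"), ("E", "quarter"), ("D", "quarter"),
    ("C", "quarter"), ("C", "quarter"), ("D", "quarter"), ("E", "quarter"),
    ("E", "quarter"), ("D", "quarter"), ("D", "half"),
]


def note_song(score: Sequence[tuple], time_scale: float = 1.0) -> Supervisor:
    """5-dim note-pulse supervisor from a monophonic C–G score.

    Each quarter note is the positive half of a 2 Hz sine (0.25 s pulse),
    each half note the positive half of a 1 Hz sine (0.5 s pulse), placed
    in the component of its note.  ``time_scale`` stretches the song
    (durations multiply by it).
    """
    if not score:
        raise ValueError("score must be non-empty")
    starts, durs, comps = [], [], []
    t0 = 0.0
    for note, kind in score:
        if note not in _NOTE_INDEX:
            raise ValueError(f"unknown note symbol {note!r}")
        if kind not in ("quarter", "half"):
            raise ValueError(f"unknown duration {kind!r}")
        dur = (0.25 if kind == "quarter" else 0.5) * time_scale
        starts.append(t0)
        durs.append(dur)
        comps.append(_NOTE_INDEX[note])
        t0 += dur
    starts_a = np.asarray(starts)
    durs_a = np.asarray(durs)
    comps_a = np.asarray(comps)
    T = float(t0)

    def fn(t):
        tau = np.mod(t, T)
        out = np.zeros((t.size, 5))
        idx = np.searchsorted(starts_a, tau, side="right") - 1
        idx = np.clip(idx, 0, len(starts_a) - 1)
        local = tau - starts_a[idx]
        inside = local < durs_a[idx]
        val = np.sin(np.pi * local / durs_a[idx])
        out[np.arange(t.size), comps_a[idx]] = np.where(inside, val, 0.0)
        return out

    return Supervisor(m=5, T=T, fn=fn, label="note_song")


@dataclass
class HDTSSpec:
    """High-dimensional temporal signal: T split into m subintervals with
    one pulse per subinterval (``shape``: 'sine' or 'gaussian')."""

    T: float
    m: int
    shape: str = "sine"
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.shape not in ("sine", "gaussian"):
            raise ValueError("shape must be 'sine' or 'gaussian'")
        if self.shape == "gaussian" and self.sigma is None:
            # pulses should roughly tile the interval: σ ~ subinterval/4
            self.sigma = self.T / (4.0 * self.m)

    @property
    def centers(self) -> np.ndarray:
        n = np.arange(1, self.m + 1)
        return self.T * (2 * n - 1) / (2 * self.m)


def hdts(spec: HDTSSpec, periodic: bool = True) -> Supervisor:
    """Build the HDTS supervisor for ``spec``.

    Sine shape: x_n(t) = |sin(mπt/T)| for t ∈ I_n, 0 otherwise — exactly
    one component is nonzero at any interior time and the pulses tile
    [0, T].  Gaussian shape: unit-height bumps at the interval centers.
    """
    T, m = spec.T, spec.m

    if spec.shape == "sine":
        def fn(t):
            tau = np.mod(t, T) if periodic else t
            out = np.zeros((t.size, m))
            idx = np.clip((tau * m / T).astype(int), 0, m - 1)
            ok = (tau >= 0) & (tau <= T)
            out[np.arange(t.size), idx] = np.where(
                ok, np.abs(np.sin(m * np.pi * tau / T)), 0.0)
            return out
    else:
        centers = spec.centers
        sig = spec.sigma

        def fn(t):
            tau = np.mod(t, T) if periodic else t
            return np.exp(-((tau[:, None] - centers[None, :]) ** 2)
                          / sig ** 2)

    return Supervisor(m=m, T=T, fn=fn, label=f"hdts_{spec.shape}_{m}",
                      periodic=periodic)


def pulse_chain(K: int, period: float = 20.0,
                periodic: bool = True) -> Supervisor:
    """K-dim chain of contiguous positive sinusoid half-waves.

    Component n carries the positive half (width period/2) of a sinusoid
    of the given period, active n-th; the half-waves are non-overlapping
    and tile the total duration K·period/2 (e.g. 500 pulses of a 20 ms
    period span 5 s).  Equivalent to a sine-shaped HDTS with m = K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sup = hdts(HDTSSpec(T=K * period / 2.0, m=K, shape="sine"),
               periodic=periodic)
    sup.label = f"pulse_chain_{K}"
    return sup


def moving_blob(n_side: int = 8, T: float = 2.0, sigma: Optional[float] = None,
                radius: Optional[float] = None) -> Supervisor:
    """Synthetic pixel movie: a Gaussian blob orbiting the frame center.

    Output dimension n_side², values in [0, 1]; one orbit per period T.
    A smooth, high-dimensional, temporally structured stand-in for natural
    movie supervisors: the default blob width (0.22·n_side) and orbit
    radius (0.25·n_side) give per-pixel autocorrelation times of a few
    hundred ms at T = 2 s, in the range of natural-scene pixel dynamics
    (most of a natural frame changes slowly between frames).
    """
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    c = (n_side - 1) / 2.0
    sigma = sigma if sigma is not None else 0.22 * n_side
    rad = radius if radius is not None else n_side / 4.0
    yy, xx = np.mgrid[0:n_side, 0:n_side]
    px = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    def fn(t):
        ang = 2 * np.pi * np.mod(t, T) / T
        cx = c + rad * np.cos(ang)
        cy = c + rad * np.sin(ang)
        d2 = ((px[None, :, 0] - cx[:, None]) ** 2
              + (px[None, :, 1] - cy[:, None]) ** 2)
        return np.exp(-d2 / (2 * sigma ** 2))

    return Supervisor(m=n_side * n_side, T=T, fn=fn,
                      label=f"moving_blob_{n_side}x{n_side}")


def stack(*sups: Supervisor, T: Optional[float] = None) -> Supervisor:
    """Concatenate supervisors along the output dimension (e.g. a song
    plus its internally generated HDTS)."""
    if not sups:
        raise ValueError("need at least one supervisor")
    T = T if T is not None else max(s.T for s in sups)
    m = sum(s.m for s in sups)

    def fn(t):
        return np.concatenate([np.atleast_2d(s(t)) for s in sups], axis=1)

    return Supervisor(m=m, T=T, fn=fn,
                      label="+".join(s.label for s in sups),
                      periodic=all(s.periodic for s in sups))


def sample_to_table(sup: Supervisor, t: np.ndarray) -> np.ndarray:
    """Columnar (t, x₁…x_m) samples for export/inspection."""
    x = np.atleast_2d(sup(t))
    return np.column_stack([t, x])
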