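"""Synaptic spike filters, static chaotic weights, and the weight decomposition.

Spikes are filtered into continuous, current-like variables r_j.  The double
exponential filter

    dr/dt = -r/τ_d + h,    dh/dt = -h/τ_r + Σ_k δ(t - t_k)/(τ_r τ_d)

delivers unit area per spike (∫ r dt = 1); the single-exponential filter
increments r by 1/τ_s per spike, and the alpha synapse is the τ_r = τ_d
limit of the double exponential.  Decay is applied exactly
(multiplicatively, exp(-dt/τ)) each step — filters are linear, so this
removes a needless dt artifact — while the h → r coupling term uses an
Euler quadrature.  Spike increments are discrete jumps at the spike step.

The recurrent weight matrix decomposes as ω = G ω⁰ + Q η φᵀ: a sparse
static matrix ω⁰ that places the network in the chaotic regime, scaled by
G, plus a rank-m learned feedback term built from the random encoders η
(entries uniform on [-1, 1]) and the learned decoders φ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SynapseParams",
    "FilterState",
    "WeightConfig",
    "update_filter",
    "build_static_weights",
    "build_encoders",
    "effective_weights",
    "suggested_Q",
]


@dataclass
class SynapseParams:
    """Synaptic filter kind and time constants (same unit as the run)."""

    kind: str = "double_exp"
    tau_s: float = 20.0     # single-exponential constant
    tau_r: float = 2.0      # rise
    tau_d: float = 20.0     # decay

    def __post_init__(self) -> None:
        if self.kind not in ("single_exp", "double_exp", "alpha"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if min(self.tau_s, self.tau_r, self.tau_d) <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.kind == "alpha":
            self.tau_d = self.tau_r

    @property
    def is_single(self) -> bool:
        return self.kind == "single_exp"


@dataclass
class FilterState:
    """Filtered output r and (double-exp only) auxiliary rise variable h."""

    r: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, N: int) -> "FilterState":
        return cls(np.zeros(N), np.zeros(N))


def update_filter(fs: FilterState, spikes: np.ndarray, dt: float,
                  params: SynapseParams) -> FilterState:
    """Advance the synaptic filter one step.

    ``spikes`` is a boolean (or 0/1) array.  For the double exponential the
    spike impulse is added to h at the start of the step and the pair is
    then propagated exactly over dt (the cascade is linear, so the coupling
    integral ∫ exp(-(dt-s)/τ_d) exp(-s/τ_r) ds has a closed form); a spike
    therefore begins to influence r within its own step and the discrete
    area Σ r·dt per spike is correct to O(dt²).  The single-exponential
    filter jumps by 1/τ_s at the spike step after its decay.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spikes = np.asarray(spikes, dtype=float)
    if params.is_single:
        r = fs.r * np.exp(-dt / params.tau_s) + spikes / params.tau_s
        return FilterState(r, fs.h)
    tau_r, tau_d = params.tau_r, params.tau_d
    e_r = np.exp(-dt / tau_r)
    e_d = np.exp(-dt / tau_d)
    if abs(tau_d - tau_r) > 1e-12 * tau_d:
        c = tau_r * tau_d * (e_d - e_r) / (tau_d - tau_r)
    else:
        c = dt * e_d
    h_plus = fs.h + spikes / (tau_r * tau_d)
    r = fs.r * e_d + h_plus * c
    h = h_plus * e_r
    return FilterState(r, h)


def build_static_weights(N: int, p: float, model: str = "lif",
                         seed: int | np.random.Generator = 0,
                         variance: str = "auto",
                         mean_zero: Optional[bool] = None,
                         per_row: bool = False,
                         scale: float = 1.0) -> sp.csc_matrix:
    """Sparse static matrix ω⁰ with Normal(0, σ²) nonzero entries.

    ``variance`` selects the scaling of the nonzero entries:

    * ``"np2"`` — σ² = (N p²)⁻¹, i.e. std 1/(p √N).  This is the convention
      the working parameter sets in :mod:`spikeforce.experiments` assume
      (it makes the printed chaos-onset gains G come out right), and the
      stated convention for the rate model.
    * ``"np"`` — σ² = (N p)⁻¹, the convention stated for the spiking
      models in the original description; kept selectable for sensitivity
      checks.
    * ``"auto"`` — ``"np2"``.

    For the LIF and theta models the sample mean of the nonzero entries is
    explicitly subtracted (globally by default, per row with
    ``per_row=True``) to counterbalance firing-rate heterogeneity; the
    Izhikevich and rate matrices are left uncorrected.  ``scale``
    multiplies the resulting std (the rate-network benchmark uses
    scale = 1/F so that the static fluctuations stay commensurate with the
    O(1) feedback after the type-I transfer r = F√s amplifies currents).
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not (0.0 < p <= 1.0):
        raise ValueError("sparsity p must lie in (0, 1]")
    if variance == "auto":
        variance = "np2"
    if variance == "np":
        sigma = 1.0 / np.sqrt(N * p)
    elif variance == "np2":
        sigma = 1.0 / (p * np.sqrt(N))
    else:
        raise ValueError("variance must be 'np', 'np2' or 'auto'")
    sigma *= scale
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mask = rng.random((N, N)) < p
    w = np.zeros((N, N))
    n_nz = int(mask.sum())
    w[mask] = rng.normal(0.0, sigma, size=n_nz)
    if mean_zero is None:
        mean_zero = model in ("lif", "theta")
    if mean_zero and n_nz:
        if per_row:
            for i in range(N):
                row = mask[i]
                if row.any():
                    w[i, row] -= w[i, row].mean()
        else:
            w[mask] -= w[mask].mean()
    return sp.csc_matrix(w)


def build_encoders(N: int, m: int,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Encoders η: N×m, entries uniform on [-1, 1]."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(N, m))


@dataclass
class WeightConfig:
    """Static chaotic matrix plus feedback decomposition parameters.

    ``omega0`` and ``eta`` are built lazily by :meth:`realize` (sparse CSC
    and dense N×m).  ``sigma_omega`` records the std of the nonzero ω⁰
    entries for use in the Q heuristic.
    """

    N: int
    p: float = 0.1
    G: float = 1.0
    Q: float = 1.0
    seed: int = 0
    variance: str = "auto"
    mean_zero: Optional[bool] = None
    per_row: bool = False
    scale: float = 1.0
    omega0: Optional[sp.csc_matrix] = None
    eta: Optional[np.ndarray] = None
    sigma_omega: float = field(default=0.0)

    def realize(self, model: str, m: int) -> "WeightConfig":
        rng = np.random.default_rng(self.seed)
        if self.omega0 is None:
            self.omega0 = build_static_weights(
                self.N, self.p, model=model, seed=rng,
                variance=self.variance, mean_zero=self.mean_zero,
                per_row=self.per_row, scale=self.scale)
        if self.eta is None or self.eta.shape[1] != m:
            self.eta = build_encoders(self.N, m, seed=rng)
        nz = self.omega0.data
        self.sigma_omega = float(nz.std()) if nz.size else 0.0
        return self

    def save(self, path) -> None:
        """Portable array container with metadata."""
        np.savez_compressed(
            path, indptr=self.omega0.indptr, indices=self.omega0.indices,
            data=self.omega0.data, shape=np.array(self.omega0.shape),
            eta=self.eta,
            meta=np.array([self.N, self.p, self.G, self.Q, self.seed]))

    @classmethod
    def load(cls, path) -> "WeightConfig":
        z = np.load(path)
        N, p, G, Q, seed = z["meta"]
        cfg = cls(N=int(N), p=float(p), G=float(G), Q=float(Q),
                  seed=int(seed))
        cfg.omega0 = sp.csc_matrix(
            (z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"]))
        cfg.eta = z["eta"]
        cfg.sigma_omega = float(cfg.omega0.data.std())
        return cfg


def effective_weights(omega0: sp.spmatrix | np.ndarray, G: float, Q: float,
                      eta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Dense effective matrix ω = G ω⁰ + Q η φᵀ."""
    eta = np.atleast_2d(eta)
    phi = np.atleast_2d(phi)
    if eta.shape != phi.shape:
        raise ValueError(f"shape mismatch: eta {eta.shape} vs phi {phi.shape}")
    w0 = omega0.toarray() if sp.issparse(omega0) else np.asarray(omega0)
    if w0.shape[0] != eta.shape[0]:
        raise ValueError("omega0 and eta row counts differ")
    return G * w0 + Q * eta @ phi.T

def suggested_Q(G: float, sigma_omega: float, rate_rms: float,
                c: float = 1.0) -> float:
    """Order-of-magnitude feedback gain Q = c · G · σ_ω · √⟨r²⟩.

    Balances the fluctuations of the learned feedback term against those of
    the static chaotic input (c = 1 by default; the estimate is meant to be
    right to within an order of magnitude, not a tuned constant).
    """
    if min(G, sigma_omega, rate_rms) < 0:
        raise ValueError("arguments must be non-negative")
    return c * G * sigma_omega * rate_rms
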