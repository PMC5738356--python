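"""Post-training manipulations of frozen trained networks.

Three families of manipulation, all applied after learning with the
decoders frozen:

* **excitation/inhibition rescaling** — the positive entries of the
  *effective* weight matrix ω = G ω⁰ + Q η φᵀ are multiplied by a factor
  α ≥ 0 while negative entries are untouched: α > 1 shifts the balance
  toward excitation, α < 1 toward inhibition (the α abstraction of a
  bicuculline-style manipulation).
* **HDTS transforms** — compression of the time axis (faster replay),
  reversal of the component order (reverse replay; the dynamics inside a
  pulse are not reversed), and amplitude attenuation.
* **lesioning** — removal of a random subset of neurons; by default full
  removal (incoming and outgoing recurrent weights, encoders and decoder
  rows all zeroed), or output-only silencing with ``mode='output'``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .supervisors import Supervisor

__all__ = [
    "PerturbationSpec",
    "scale_excitatory",
    "transform_hdts",
    "lesion_indices",
    "lesion_neurons",
]


@dataclass
class PerturbationSpec:
    """Bundle of perturbation settings for sweep drivers."""

    alpha: float = 1.0
    compression: float = 1.0
    reverse: bool = False
    hdts_amplitude: float = 1.0
    lesion_fraction: float = 0.0
    lesion_target: str = "replay"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.compression <= 0:
            raise ValueError("compression must be > 0")
        if self.hdts_amplitude < 0:
            raise ValueError("hdts_amplitude must be >= 0")
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.lesion_target not in ("replay", "hdts"):
            raise ValueError("lesion_target must be 'replay' or 'hdts'")


def scale_excitatory(omega: np.ndarray | sp.spmatrix,
                     alpha: float) -> np.ndarray | sp.spmatrix:
    """ω' = α (ω)₊ + (ω)₋ on the effective matrix.

    Positive entries are multiplied by α; non-positive entries are returned
    bit-identical (α = 1 is the identity, α = 0 zeroes every positive
    entry).  Works on dense or sparse matrices.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sp.issparse(omega):
        out = omega.copy().tocsr()
        pos = out.data > 0
        out.data[pos] = alpha * out.data[pos]
        return out
    out = np.array(omega, copy=True)
    pos = out > 0
    out[pos] = alpha * out[pos]
    return out


def transform_hdts(sup: Supervisor, compression: float = 1.0,
                   reverse: bool = False,
                   amplitude: float = 1.0) -> Supervisor:
    """Compress, reverse and/or attenuate an HDTS-style supervisor.

    Compression scales the time axis by 1/compression (a pulse centered at
    c moves to c/compression; the total duration becomes T/compression).
    Reversal flips the *order of the components*, so the assemblies fire
    in reverse sequence while each pulse keeps its internal shape.  The
    transform is invertible: applying (1/compression, reverse, 1/amplitude)
    recovers the original samples.
    """
    if compression <= 0:
        raise ValueError("compression must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")

    def fn(t):
        out = np.atleast_2d(sup(t * compression))
        if reverse:
            out = out[:, ::-1]
        return amplitude * out

    return Supervisor(m=sup.m, T=sup.T / compression, fn=fn,
                      label=f"{sup.label}|c{compression}"
                            f"{'r' if reverse else ''}a{amplitude}",
                      periodic=sup.periodic)


def lesion_indices(N: int, fraction: float,
                   seed: int = 0) -> np.ndarray:
    """Seedable random choice of ⌈fraction·N⌉ neurons to remove."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    n = int(np.ceil(fraction * N))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(N, size=n, replace=False))


def lesion_neurons(weights, decoder=None, w_in: Optional[np.ndarray] = None,
                   fraction: float = 0.0, seed: int = 0,
                   mode: str = "full"):
    """Remove a random subset of neurons from a trained network.

    Returns ``(weights', decoder', w_in')`` — deep copies with the selected
    neurons' incoming and outgoing static weights, encoder rows, decoder
    rows and feedforward input rows zeroed (``mode='full'``), or only their
    decoder rows (``mode='output'``).  Idempotent for a fixed seed and
    fraction.
    """
    if mode not in ("full", "output"):
        raise ValueError("mode must be 'full' or 'output'")
    idx = lesion_indices(weights.N, fraction, seed)
    w2 = copy.deepcopy(weights)
    d2 = copy.deepcopy(decoder) if decoder is not None else None
    win2 = w_in.copy() if w_in is not None else None
    if idx.size:
        if mode == "full":
            if w2.omega0 is not None:
                dense = w2.omega0.toarray()
                dense[idx, :] = 0.0
                dense[:, idx] = 0.0
                w2.omega0 = sp.csc_matrix(dense)
            if w2.eta is not None:
                w2.eta = w2.eta.copy()
                w2.eta[idx, :] = 0.0
            if win2 is not None:
                win2[idx, :] = 0.0
        if d2 is not None:
            d2.phi = d2.phi.copy()
            d2.phi[idx, :] = 0.0
    return w2, d2, win2
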