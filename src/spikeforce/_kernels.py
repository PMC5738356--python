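"""Compiled inner loops for whole-network simulation.

One numba kernel advances a network for a chunk of steps (typically the
interval between two RLS updates).  Semantics match the numpy steppers in
:mod:`spikeforce.neurons` and the filter update in
:mod:`spikeforce.synapses` exactly; a test asserts step-for-step agreement.

Per integration step the kernel

1. integrates each neuron with the current assembled from the static
   recurrent input, the feedback Q η · x̂ (recomputed from the *current*
   approximant every step), the bias and any external feedforward current
   (all filtered quantities are the values at the end of the previous
   step),
2. on spikes, adds the discrete jumps into the rise variables: the
   presynaptic column of G ω⁰/(τ_r τ_d) into the static-input filter,
   1/(τ_r τ_d) into the neuron's own decoding filter, and φ_j/(τ_r τ_d)
   into the tracked approximant projection,
3. propagates the filter pairs exactly over dt (exponential decay for h,
   exponential decay plus the closed-form cascade coupling for r).

The approximant x̂ = φᵀ r is not recomputed as an N×m product per step;
because the filter is linear, y1 = φᵀ r and y2 = φᵀ h obey the same scalar
recurrences and are updated in O(m + spikes·m) per step.  The driver
refreshes them from scratch at every chunk boundary (and whenever φ
changes) so floating-point drift cannot accumulate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_THETA = 0
MODEL_LIF = 1
MODEL_IZH = 2

_PI = np.pi
_TWO_PI = 2.0 * np.pi
_PI2 = np.pi ** 2


@njit(cache=True)
def run_chunk(model, n_steps, step0, dt,
              v, u, refrac,
              Ips, Hps, r, hr,
              y1, y2,
              indptr, indices, wdata,
              etaQ, phi,
              I_bias,
              Eext,
              single_exp, e_r, e_d, cpl, inv_jump,
              C, kk, v_r, v_t, v_reset, v_peak, a, b, d, tau_m, tau_ref,
              del_neuron, del_step,
              spk_step, spk_id):
    """Advance the network ``n_steps`` steps; returns the spike count.

    ``wdata`` must already be scaled by G/(τ_r τ_d) (double-exp) or G/τ_s
    (single-exp); ``inv_jump`` is the matching per-spike jump for the
    decoding filter and ``cpl`` the exact h→r coupling over one step.
    ``Eext`` is an (n_steps, N) per-step external current, or a (0, 0)
    array when absent.  A spike of ``del_neuron`` at global step
    ``del_step`` is suppressed: not recorded, not transmitted (the
    neuron's own reset still applies).
    """
    N = v.shape[0]
    m = y1.shape[0]
    use_ext = Eext.shape[0] == n_steps
    nsp = 0
    for s in range(n_steps):
        gstep = step0 + s
        chunk_first = nsp  # spikes of this step start here
        # 1. integrate neurons; currents use filter state from prev step
        for i in range(N):
            I = I_bias + Ips[i]
            for q in range(m):
                I += etaQ[i, q] * y1[q]
            if use_ext:
                I += Eext[s, i]
            spiked = False
            if model == MODEL_THETA:
                th = v[i]
                cth = np.cos(th)
                th = th + dt * ((1.0 - cth) + _PI2 * (1.0 + cth) * I)
                if th >= _PI:
                    spiked = True
                    th -= _TWO_PI
                    if th >= _PI:  # pathological step; wrap w/o extra spike
                        th = np.mod(th + _PI, _TWO_PI) - _PI
                elif th < -_PI:
                    th = np.mod(th + _PI, _TWO_PI) - _PI
                v[i] = th
            elif model == MODEL_LIF:
                if refrac[i] > 0.0:
                    refrac[i] -= dt
                    v[i] = v_reset
                else:
                    vv = v[i] + dt * (-v[i] + I) / tau_m
                    if vv >= v_t:
                        spiked = True
                        vv = v_reset
                        refrac[i] = tau_ref
                    v[i] = vv
            else:  # Izhikevich
                vv = v[i]
                uu = u[i]
                vn = vv + dt * (kk * (vv - v_r) * (vv - v_t) - uu + I) / C
                un = uu + dt * a * (b * (vv - v_r) - uu)
                if vn >= v_peak:
                    spiked = True
                    vn = v_reset
                    un += d
                v[i] = vn
                u[i] = un
            if spiked:
                if gstep == del_step and i == del_neuron:
                    continue  # deleted spike: silent, untransmitted
                spk_step[nsp] = gstep
                spk_id[nsp] = i
                nsp += 1
        # 2. spike jumps into the rise variables (h) / single-exp handled
        #    after decay below
        if not single_exp:
            for k in range(chunk_first, nsp):
                j = spk_id[k]
                for idx in range(indptr[j], indptr[j + 1]):
                    Hps[indices[idx]] += wdata[idx]
                hr[j] += inv_jump
                for q in range(m):
                    y2[q] += phi[j, q] * inv_jump
            # 3. exact propagation of the (r, h) pairs over dt
            for i in range(N):
                Ips[i] = Ips[i] * e_d + Hps[i] * cpl
                Hps[i] *= e_r
                r[i] = r[i] * e_d + hr[i] * cpl
                hr[i] *= e_r
            for q in range(m):
                y1[q] = y1[q] * e_d + y2[q] * cpl
                y2[q] *= e_r
        else:
            for i in range(N):
                Ips[i] *= e_d
                r[i] *= e_d
            for q in range(m):
                y1[q] *= e_d
            for k in range(chunk_first, nsp):
                j = spk_id[k]
                for idx in range(indptr[j], indptr[j + 1]):
                    Ips[indices[idx]] += wdata[idx]
                r[j] += inv_jump
                for q in range(m):
                    y1[q] += phi[j, q] * inv_jump
    return nsp
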