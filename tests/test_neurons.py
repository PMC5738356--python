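"""Single-neuron dynamics: fixed points, closed-form rates, reset rules."""

import numpy as np
import pytest

from spikeforce.neurons import (NeuronParams, NetworkState, initial_state,
                                rate_transfer, step_izhikevich, step_lif,
                                step_rate_network, step_theta)
from spikeforce.synapses import SynapseParams, WeightConfig
from spikeforce import rls


def _run_single(params, I, duration, dt, model_kwargs=None):
    """Drive one uncoupled neuron with constant current via the kernel
    (G=0 so the 2-neuron network is uncoupled)."""
    p = params
    p.I_bias = I
    w = WeightConfig(N=2, p=0.5, G=0.0, Q=0.0, seed=0)
    res = rls.simulate(p, w, SynapseParams(), duration, dt, seed=5)
    ts = res.spike_times[res.spike_ids == 0]
    return ts


class TestTheta:
    def test_rest_is_fixed_point(self):
        st = NetworkState(v=np.zeros(3), u=np.zeros(3), refrac=np.zeros(3))
        new, spikes = step_theta(st, np.zeros(3), dt=0.01)
        assert not spikes.any()
        assert np.allclose(new.v, 0.0)

    @pytest.mark.parametrize("I", [0.01, 0.04, 0.16])
    def test_rate_matches_sqrt_I(self, I):
        # firing rate of the theta/QIF neuron under constant drive is √I
        # per unit time (period π/√(π² I))
        ts = _run_single(NeuronParams.theta(), I, duration=400.0, dt=0.01)
        rate = (ts.size - 1) / (ts[-1] - ts[0])
        assert abs(rate - np.sqrt(I)) / np.sqrt(I) < 0.02

    def test_wrap_on_crossing(self):
        st = NetworkState(v=np.array([np.pi - 1e-3]), u=np.zeros(1),
                          refrac=np.zeros(1))
        new, spikes = step_theta(st, np.array([10.0]), dt=0.05)
        assert spikes.sum() == 1
        assert -np.pi < new.v[0] <= np.pi


class TestLIF:
    def test_threshold_asymptote_never_spikes(self):
        p = NeuronParams.lif()
        st = NetworkState(v=np.full(1, p.v_reset), u=np.zeros(1),
                          refrac=np.zeros(1))
        I = np.array([p.v_t])  # v -> v_t asymptotically
        for _ in range(5000):
            st, spikes = step_lif(st, I, 0.5, p)
            assert not spikes.any()
        assert st.v[0] < p.v_t

    @pytest.mark.parametrize("dt", [0.5, 0.05])
    def test_isi_closed_form(self, dt):
        # ISI = τ_ref + τ_m ln((I - v_reset)/(I - v_t)) for constant I
        p = NeuronParams.lif()
        ts = _run_single(p, -30.0, duration=2000.0, dt=dt)
        isi = np.diff(ts)
        theory = 2.0 + 10.0 * np.log(3.5)
        assert np.all(np.abs(isi - theory) <= dt + 1e-9)

    def test_refractory_contract(self):
        p = NeuronParams.lif()
        ts = _run_single(p, -20.0, duration=500.0, dt=0.1)
        assert np.diff(ts).min() >= p.tau_ref - 1e-9


class TestIzhikevich:
    def test_rest_state_stationary(self):
        p = NeuronParams.izhikevich()
        p.b = 0.0
        st = NetworkState(v=np.full(2, p.v_r), u=np.zeros(2),
                          refrac=np.zeros(2))
        new, spikes = step_izhikevich(st, np.zeros(2), 0.04, p)
        assert not spikes.any()
        assert np.allclose(new.v, p.v_r)
        assert np.allclose(new.u, 0.0)

    def test_reset_and_adaptation_jump(self):
        p = NeuronParams.izhikevich()
        st = NetworkState(v=np.array([29.9]), u=np.array([50.0]),
                          refrac=np.zeros(1))
        new, spikes = step_izhikevich(st, np.array([5000.0]), 0.04, p)
        assert spikes.all()
        assert new.v[0] == p.v_reset == -65.0
        # u gains the discrete d = 200 pA on top of its Euler update
        assert new.u[0] == pytest.approx(50.0 + p.d, abs=0.1)

    def test_steady_rate_dt_convergence(self):
        # coarse step (0.04) within 2% of a 40x finer reference (0.001)
        p = NeuronParams.izhikevich()
        rates = []
        for dt in (0.04, 0.001):
            ts = _run_single(NeuronParams.izhikevich(), 2000.0,
                             duration=2000.0, dt=dt)
            rates.append((ts.size - 1) / (ts[-1] - ts[0]))
        assert abs(rates[0] - rates[1]) / rates[1] < 0.02


class TestRate:
    def test_transfer_branches_and_monotonicity(self):
        assert rate_transfer(1.0, 10.0) == pytest.approx(10.0)
        assert rate_transfer(-0.5, 10.0) == 0.0
        s = np.linspace(-1, 4, 101)
        r = rate_transfer(s, 7.0)
        assert np.all(np.diff(r) >= 0)

    def test_exponential_decay_and_fixed_point(self):
        s = np.array([2.0])
        dt, tau = 0.01, 10.0
        for _ in range(int(30 / dt)):
            s = step_rate_network(s, np.zeros(1), dt, tau)
        assert s[0] == pytest.approx(2.0 * np.exp(-30 / tau), rel=5e-3)
        for _ in range(int(200 / dt)):
            s = step_rate_network(s, np.full(1, 3.5), dt, tau)
        assert s[0] == pytest.approx(3.5, rel=1e-6)


class TestKernelEquivalence:
    """The numba kernel must reproduce the numpy steppers exactly."""

    @pytest.mark.parametrize("model", ["theta", "lif", "izhikevich"])
    def test_chunk_matches_numpy_steps(self, model, rng):
        from spikeforce import _kernels as K
        from spikeforce.synapses import update_filter, FilterState

        N, n_steps, dt = 40, 60, 0.1
        params = {"theta": NeuronParams.theta,
                  "lif": NeuronParams.lif,
                  "izhikevich": NeuronParams.izhikevich}[model]()
        params.I_bias = {"theta": 0.05, "lif": -35.0,
                         "izhikevich": 1500.0}[model]
        syn = SynapseParams(tau_r=2.0, tau_d=20.0)
        w = WeightConfig(N=N, p=0.3, G=1.0, Q=0.5, seed=3)
        w.realize(model, 1)
        phi = rng.normal(0, 0.1, size=(N, 1))
        state = initial_state(params, N, np.random.default_rng(9))

        # --- numpy reference: neuron step with currents from the
        # previous step's filters, then the shared update_filter
        # semantics for the decoding filter and (weighted spikes) the
        # static-input filter
        v = state.v.copy()
        u = state.u.copy()
        refrac = state.refrac.copy()
        fs_r = FilterState.zeros(N)       # decoding filter
        fs_s = FilterState.zeros(N)       # static-input filter (weighted)
        inv = 1.0 / (syn.tau_r * syn.tau_d)
        e_r = np.exp(-dt / syn.tau_r)
        e_d = np.exp(-dt / syn.tau_d)
        c = syn.tau_r * syn.tau_d * (e_d - e_r) / (syn.tau_d - syn.tau_r)
        Gw = (w.G * w.omega0).toarray()
        etaQ = w.Q * w.eta
        step_fn = {"theta": step_theta, "lif": step_lif,
                   "izhikevich": step_izhikevich}[model]
        ref_spikes = []
        for _ in range(n_steps):
            xhat = phi.T @ fs_r.r
            I = params.I_bias + fs_s.r + (etaQ @ xhat)
            st = NetworkState(v=v, u=u, refrac=refrac)
            st, spikes = step_fn(st, I, dt, params)
            v, u, refrac = st.v, st.u, st.refrac
            ref_spikes.append(spikes.copy())
            fs_r = update_filter(fs_r, spikes, dt, syn)
            h_plus = fs_s.h + Gw.T[spikes].sum(axis=0) * inv
            fs_s = FilterState(fs_s.r * e_d + h_plus * c, h_plus * e_r)
        Ips = fs_s.r

        # --- kernel
        state2 = initial_state(params, N, np.random.default_rng(9))
        v2 = state2.v.copy()
        u2 = state2.u.copy()
        refrac2 = state2.refrac.copy()
        Ips2 = np.zeros(N)
        Hps2 = np.zeros(N)
        r2 = np.zeros(N)
        hr2 = np.zeros(N)
        y1 = phi.T @ r2
        y2 = phi.T @ hr2
        w0 = w.omega0.tocsc()
        spk_s = np.empty(N * n_steps, dtype=np.int64)
        spk_i = np.empty(N * n_steps, dtype=np.int64)
        model_id = {"theta": K.MODEL_THETA, "lif": K.MODEL_LIF,
                    "izhikevich": K.MODEL_IZH}[model]
        nsp = K.run_chunk(
            model_id, n_steps, 0, dt, v2, u2, refrac2, Ips2, Hps2, r2, hr2,
            y1, y2, w0.indptr.astype(np.int64), w0.indices.astype(np.int64),
            (w.G * w0.data * inv), np.ascontiguousarray(etaQ), phi,
            params.I_bias, np.zeros((0, 0)), False, e_r, e_d, c, inv,
            params.C, params.k, params.v_r, params.v_t, params.v_reset,
            params.v_peak, params.a, params.b, params.d, params.tau_m,
            params.tau_ref, -1, -1, spk_s, spk_i)

        ref_total = int(sum(s.sum() for s in ref_spikes))
        assert nsp == ref_total
        np.testing.assert_allclose(v2, v, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(r2, fs_r.r, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(Ips2, Ips, rtol=1e-10, atol=1e-13)


def test_initial_state_seedable_and_in_range():
    p = NeuronParams.izhikevich()
    a = initial_state(p, 100, np.random.default_rng(5))
    b = initial_state(p, 100, np.random.default_rng(5))
    np.testing.assert_array_equal(a.v, b.v)
    assert a.v.min() >= p.v_reset and a.v.max() <= 30.0
    th = initial_state(NeuronParams.theta(), 100, np.random.default_rng(5))
    assert th.v.min() > -np.pi and th.v.max() <= np.pi
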