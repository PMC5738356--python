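"""Teaching-signal generators: oscillators, chaotic systems, songs, HDTS."""

import numpy as np
import pytest

from spikeforce import supervisors as sup
from spikeforce.supervisors import HDTSSpec


class TestOscillators:
    def test_sinusoid_zeros_and_period(self):
        s = sup.sinusoid(5.0)
        assert s(0.0)[0] == pytest.approx(0.0, abs=1e-12)
        assert s(0.1)[0] == pytest.approx(0.0, abs=1e-9)  # half period
        t = np.linspace(0, 1, 50)
        np.testing.assert_allclose(s(t), s(t + s.T), atol=1e-9)

    def test_sawtooth_ramp(self):
        s = sup.sawtooth(2.0)
        t = np.array([0.0, 0.125, 0.25, 0.4999])
        np.testing.assert_allclose(s(t)[:, 0], [-1.0, -0.5, 0.0, 0.9996],
                                   atol=1e-3)

    def test_product_of_sines_values_and_period(self):
        s = sup.product_of_sines(4.0, 6.0)
        assert s.T == pytest.approx(0.5)
        t = np.linspace(0, 2, 101)
        np.testing.assert_allclose(
            s(t)[:, 0], np.sin(2 * np.pi * 4 * t) * np.sin(2 * np.pi * 6 * t),
            atol=1e-12)

    def test_product_noise_variance(self):
        s = sup.product_of_sines(4.0, 6.0, noise_sd=0.05, seed=3)
        clean = sup.product_of_sines(4.0, 6.0)
        t = np.linspace(0, 10, 20001)
        resid = s(t)[:, 0] - clean(t)[:, 0]
        assert resid.var() == pytest.approx(0.0025, rel=0.1)


class TestVanDerPol:
    def test_components_within_unit_box(self):
        s = sup.van_der_pol(5.0)
        t = np.linspace(0, 5 * s.T, 4001)
        assert np.abs(s(t)).max() <= 1.0 + 1e-9

    def test_small_mu_amplitude_near_two(self):
        # classical weakly nonlinear limit-cycle amplitude is 2
        s = sup.van_der_pol(0.3)
        assert s.raw_amplitude == pytest.approx(2.0, abs=0.1)

    def test_harmonic_regime_near_sinusoidal(self):
        s = sup.van_der_pol(0.3)
        t = np.linspace(0, s.T, 512, endpoint=False)
        x = s(t)[:, 0]
        spec = np.abs(np.fft.rfft(x))
        fundamental = spec[1:].argmax() + 1
        # higher harmonics are small relative to the fundamental
        others = np.delete(spec[1:], fundamental - 1)
        assert others.max() < 0.1 * spec[fundamental]

    def test_speedup_factor(self):
        slow = sup.van_der_pol(0.3, speed=1.0)
        fast = sup.van_der_pol(0.3, speed=20.0)
        assert fast.T == pytest.approx(slow.T / 20.0, rel=1e-6)


class TestLorenz:
    def test_rhs_vanishes_at_fixed_points(self):
        B, rho = 8.0 / 3.0, 28.0
        for sx in (1, -1):
            fp = np.array([sx * np.sqrt(B * (rho - 1)),
                           sx * np.sqrt(B * (rho - 1)), rho - 1])
            np.testing.assert_allclose(sup.lorenz_rhs(fp), 0.0, atol=1e-9)
        assert np.sqrt(B * (rho - 1)) == pytest.approx(8.485, abs=0.001)

    def test_trajectory_bounded_z_positive(self):
        s = sup.lorenz(duration=40.0, seed=0)
        raw = s.raw_trajectory
        assert np.isfinite(raw).all()
        assert np.abs(raw).max() < 100.0
        assert raw[:, 2].min() > 0.0
        t = np.linspace(0, 40, 1001)
        assert np.abs(s(t)).max() <= 1.0 + 1e-9

    def test_sensitive_dependence(self):
        a = sup.lorenz(duration=30.0, seed=1)
        b = sup.lorenz(duration=30.0, seed=2)  # different initial condition
        t = np.linspace(20, 30, 200)
        assert np.abs(a(t) - b(t)).max() > 0.2


class TestNoteSong:
    def test_single_quarter_note_pulse(self):
        s = sup.note_song([("E", "quarter")])
        t = np.linspace(0, 0.25, 101)
        x = s(t)
        assert x[:, 2].max() == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(np.delete(x, 2, axis=1), 0.0)
        # positive half of a 2 Hz sine
        np.testing.assert_allclose(x[1:-1, 2],
                                   np.sin(2 * np.pi * 2.0 * t[1:-1]),
                                   atol=1e-9)

    def test_monophonic(self):
        s = sup.note_song(sup.ODE_TO_JOY)
        t = np.linspace(0, s.T, 997)
        assert ((s(t) > 1e-12).sum(axis=1) <= 1).all()

    def test_ode_to_joy_duration(self):
        assert sup.note_song(sup.ODE_TO_JOY).T == pytest.approx(4.0)
        assert sup.note_song(sup.ODE_TO_JOY_BAR1).T == pytest.approx(1.0)

    def test_unknown_note_raises(self):
        with pytest.raises(ValueError):
            sup.note_song([("H", "quarter")])


class TestHDTS:
    def test_sine_peaks_at_interval_centers(self):
        spec = HDTSSpec(T=2.0, m=8)
        s = sup.hdts(spec)
        x = s(spec.centers)
        np.testing.assert_allclose(np.diag(x), 1.0, atol=1e-9)
        np.testing.assert_allclose(x - np.diag(np.diag(x)), 0.0, atol=1e-9)

    def test_gaussian_unit_height_at_centers(self):
        spec = HDTSSpec(T=1.0, m=4, shape="gaussian")
        s = sup.hdts(spec)
        x = s(spec.centers)
        np.testing.assert_allclose(np.diag(x), 1.0, atol=1e-12)

    def test_sine_single_component_tiles_interval(self):
        spec = HDTSSpec(T=1.0, m=5)
        s = sup.hdts(spec)
        t = np.linspace(0.001, 0.999, 757)
        active = (s(t) > 1e-12).sum(axis=1)
        assert (active == 1).all()

    def test_pulse_chain_duration_and_nonoverlap(self):
        s = sup.pulse_chain(500, period=20.0)
        assert s.T == pytest.approx(5000.0)  # 500 half-waves of 10 ms
        t = np.linspace(0.01, s.T - 0.01, 2311)
        assert ((s(t) > 1e-12).sum(axis=1) <= 1).all()

    def test_pulse_chain_equal_areas(self):
        s = sup.pulse_chain(5, period=2.0)
        t = np.linspace(0, s.T, 50001)
        areas = np.trapezoid(s(t), t, axis=0)
        np.testing.assert_allclose(areas, areas[0], rtol=1e-3)


class TestMovingBlobAndUtils:
    def test_blob_dimensions_and_range(self):
        s = sup.moving_blob(16, T=1.0)
        assert s.m == 256
        x = s(np.linspace(0, 1, 64, endpoint=False))
        assert x.min() >= 0.0 and x.max() <= 1.0
        assert x.max() > 0.5  # blob actually present

    def test_stack_concatenates(self):
        a = sup.sinusoid(1.0)
        b = sup.hdts(HDTSSpec(T=1.0, m=3))
        c = sup.stack(a, b)
        assert c.m == 4
        out = c(np.array([0.3]))
        np.testing.assert_allclose(out[0, 0], a(0.3)[0])
        np.testing.assert_allclose(out[0, 1:], b(0.3))

    def test_supervisors_are_pure(self):
        s = sup.moving_blob(8)
        t = np.linspace(0, 2, 17)
        np.testing.assert_array_equal(s(t), s(t))
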