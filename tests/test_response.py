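"""Electronic and molecular Kerr response, composed forward model and the
molecular Kerr constant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thzkerr as tk
from thzkerr.pulse import FieldTrace
from thzkerr.response import (electronic_birefringence,
                              molecular_birefringence,
                              molecular_birefringence_oracle)


class TestElectronic:
    def test_worked_value(self):
        p = tk.KerrParameters(B_e=0.28e-14, tau2=1.0)
        dn = electronic_birefringence(p, 5.1e7)
        assert dn == pytest.approx(5.83e-6, rel=1e-3)

    def test_quadratic_in_field(self):
        p = tk.KerrParameters(B_e=1e-15, tau2=1.0)
        assert electronic_birefringence(p, 2.0) == pytest.approx(
            4 * electronic_birefringence(p, 1.0))
        assert electronic_birefringence(p, 0.0) == 0.0


class TestMolecular:
    dt = 0.02

    def test_zero_coefficients(self):
        p = tk.KerrParameters(tau2=1.1)
        E = np.ones(100)
        assert np.all(molecular_birefringence(p, E, self.dt) == 0)

    @pytest.mark.parametrize("tau1", [0.0, 0.5])
    def test_step_field_steady_state(self, tau1):
        p = tk.KerrParameters(B_m1=0.1e-14, B_m2=-0.3e-14, tau1=tau1,
                              tau2=0.8)
        E0 = 1e7
        dt = 0.01
        n = int(15 * p.tau2 / dt)
        E = np.full(n, E0)
        dn = molecular_birefringence(p, E, dt)
        expected = p.lambda_probe * E0**2 * (p.B_m1 + p.B_m2)
        assert dn[-1] == pytest.approx(expected, rel=1e-4)

    @given(st.floats(0.3, 3.0), st.floats(0.15, 2.0) | st.just(0.0),
           st.floats(250.0, 350.0))
    @settings(max_examples=30, deadline=None)
    def test_dc_steady_state_closed_form(self, tau2, tau1, T):
        """DC limit: lambda E^2 [(Tref/T) B_m1 + (Tref/T)^2 B_m2]."""
        p = tk.KerrParameters(B_m1=0.02e-14, B_m2=-0.3e-14, tau1=tau1,
                              tau2=tau2, T=T)
        E0 = 2e7
        dt = 0.01
        n = int(20 * max(tau2, tau1, 0.1) / dt)
        dn = molecular_birefringence(p, np.full(n, E0), dt)
        r = 296.0 / T
        expected = p.lambda_probe * E0**2 * (r * p.B_m1 + r**2 * p.B_m2)
        assert dn[-1] == pytest.approx(expected, rel=1e-3)

    def test_fast_path_matches_oracle(self):
        rng = np.random.default_rng(0)
        E = rng.standard_normal(200) * 1e7
        for tau1 in (0.0, 0.4):
            p = tk.KerrParameters(B_m1=0.1e-14, B_m2=-0.2e-14, tau1=tau1,
                                  tau2=1.1)
            fast = molecular_birefringence(p, E, 0.05)
            slow = molecular_birefringence_oracle(p, E, 0.05)
            assert np.max(np.abs(fast - slow)) < 1e-8 * np.max(np.abs(slow))

    def test_sub_step_tau1_uses_delta_limit(self):
        E = np.sin(np.arange(200) * 0.1) * 1e6
        base = tk.KerrParameters(B_m2=-0.1e-14, tau1=0.0, tau2=1.0)
        tiny = base.replace(tau1=1e-4)
        assert np.allclose(molecular_birefringence(tiny, E, self.dt),
                           molecular_birefringence(base, E, self.dt))

    def test_impulse_decay_rate(self):
        """Impulse response of the alignment term decays as exp(-t/tau2)."""
        tau2 = 1.3
        p = tk.KerrParameters(B_m1=0.1e-14, tau2=tau2)
        E = np.zeros(1000)
        E[10] = 1e7
        dn = molecular_birefringence(p, E, self.dt)
        t = self.dt * np.arange(1000)
        sel = (t > t[10] + 0.2) & (dn > 0)
        slope = np.polyfit(t[sel], np.log(dn[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau2, rel=0.01)

    def test_superposition_in_coefficients(self):
        rng = np.random.default_rng(2)
        E = rng.standard_normal(300) * 1e7
        p1 = tk.KerrParameters(B_m1=0.1e-14, tau2=1.1)
        p2 = tk.KerrParameters(B_m2=-0.2e-14, tau2=1.1)
        both = tk.KerrParameters(B_m1=0.1e-14, B_m2=-0.2e-14, tau2=1.1)
        assert np.allclose(
            molecular_birefringence(both, E, self.dt),
            molecular_birefringence(p1, E, self.dt)
            + molecular_birefringence(p2, E, self.dt), rtol=1e-12)

    def test_orientation_time_average_sign(self):
        """For any zero-area pulse the integrated orientation term carries
        the sign of B_m2."""
        rng = np.random.default_rng(42)
        dt = 0.02
        t = np.arange(0.0, 40.0, dt)
        p = tk.KerrParameters(B_m2=-0.03e-14, tau1=0.0, tau2=1.1)
        for _ in range(100):
            # random smooth zero-area pulse: derivative of a windowed signal
            tau_c = rng.uniform(0.3, 2.0)
            env = np.exp(-((t - 8.0) / 3.0) ** 2)
            carrier = np.cumsum(rng.standard_normal(t.size))
            sig = env * carrier
            E = np.gradient(sig, dt) * 1e6 / tau_c
            E -= np.trapezoid(E, t) / (t[-1] - t[0])  # enforce zero area
            dn = molecular_birefringence(p, E, dt)
            assert np.trapezoid(dn, t) < 0

    def test_temperature_scaling(self):
        """Molecular response shrinks with temperature; electronic does not."""
        rng = np.random.default_rng(3)
        E = rng.standard_normal(400) * 1e7
        mags = []
        for T in (296.0, 320.0, 341.0):
            p = tk.KerrParameters(B_m1=0.05e-14, B_m2=-0.1e-14, tau2=1.1, T=T)
            mags.append(np.max(np.abs(molecular_birefringence(p, E, 0.02))))
            pe = tk.KerrParameters(B_e=0.01e-14, tau2=1.1, T=T)
            assert np.array_equal(electronic_birefringence(pe, E),
                                  electronic_birefringence(pe.replace(T=296.0),
                                                           E))
        assert mags[0] > mags[1] > mags[2]


class TestForwardModel:
    def test_all_zero_coefficients(self, default_pulse, water_stack):
        p = tk.KerrParameters(tau2=1.1)
        fwd = tk.forward_phase_model(p, default_pulse, water_stack, n_z=8)
        assert np.all(fwd.total.phi == 0)

    def test_field_squared_scaling(self, water_stack):
        """Peak |dphi| scales as the square of the pump field."""
        p = tk.KerrParameters(B_e=0.002e-14, B_m2=-0.025e-14, tau2=1.1)
        peaks = []
        scales = np.array([0.5, 0.7, 1.0, 1.4, 2.0])
        fm = None
        for a in scales:
            pulse = tk.synth_single_cycle(a * 5.1e7, 0.25)
            fwd = tk.forward_phase_model(p, pulse, water_stack, n_z=16)
            peaks.append(np.max(np.abs(fwd.total.phi)))
        exponent = np.polyfit(np.log(scales), np.log(peaks), 1)[0]
        assert exponent == pytest.approx(2.00, abs=0.02)


class TestKerrConstant:
    @pytest.mark.parametrize("name, b_m2, expected", [
        ("water", -0.025e-14, -1.83e5),
        ("methanol", -0.018e-14, -7.2e5),
        ("ethanol", -0.0067e-14, -5.0e5),
        ("2-propanol", -0.0033e-14, -3.4e5),
    ])
    def test_printed_values(self, name, b_m2, expected):
        K = tk.molecular_kerr_constant(tk.get_material(name), b_m2)
        assert K == pytest.approx(expected, rel=0.02)

    def test_zero_coefficient(self, water):
        assert tk.molecular_kerr_constant(water, 0.0) == 0.0

    def test_missing_molar_volume(self, silica):
        with pytest.raises(ValueError, match="molar volume"):
            tk.molecular_kerr_constant(silica, -1e-16)
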