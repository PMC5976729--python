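"""Trace decomposition: parameter recovery, the electronic-coefficient
bound, temperature-derivative isolation and concentration trends."""

import numpy as np
import pytest

import thzkerr as tk
from thzkerr.fitting import concentration_trend, temperature_decomposition
from thzkerr.propagation import PhaseTrace

from conftest import small_config

B = 1e-14


def recover(cfg, kind="polar", seed=0):
    ds = tk.generate_experiment(cfg)
    model = tk.KerrModel(ds.noisy, ds.pulse, ds.stack, kind=kind,
                         n_z=cfg.n_z)
    return ds, model.fit(seed=seed)


class TestRecovery:
    def test_noiseless_polar_recovery_is_exact(self):
        cfg = small_config(tk.water_fixture, seed=0).replace(
            jitter=0.0, noise_mrad=0.0)
        ds, res = recover(cfg)
        truth = cfg.kerr
        assert res.params.B_m2 == pytest.approx(truth.B_m2, rel=1e-6)
        assert res.params.tau2 == pytest.approx(truth.tau2, rel=1e-6)
        assert res.params.B_e == pytest.approx(truth.B_e, rel=1e-4)

    def test_water_fixture_recovery(self, water_dataset):
        ds = water_dataset
        res = tk.fit_trace(ds.noisy, ds.pulse, ds.stack, kind="polar",
                           seed=7)
        assert res.converged
        assert res.params.B_m2 == pytest.approx(-0.025 * B, rel=0.05)
        assert res.params.tau2 == pytest.approx(1.1, rel=0.05)
        # component traces sum to the model trace
        assert np.allclose(res.trace_total.phi,
                           res.trace_electronic.phi + res.trace_molecular.phi)

    def test_nonpolar_recovery(self):
        cfg = small_config(lambda **kw: tk.nonpolar_fixtures(**kw)["cs2"],
                           seed=5)
        ds, res = recover(cfg, kind="nonpolar")
        assert res.params.B_e == pytest.approx(0.28 * B, rel=0.05)
        assert res.params.B_m1 == pytest.approx(0.22 * B, rel=0.05)
        assert res.params.B_e > 0 and res.params.B_m1 > 0

    def test_consistency_with_noise_level(self):
        """Median recovery error decreases as noise is reduced 3x and 10x."""
        errs = []
        for scale in (1.0, 1.0 / 3.0, 0.1):
            errors = []
            for seed in range(5):
                cfg = small_config(tk.water_fixture, seed=seed).replace(
                    jitter=0.01 * scale, noise_mrad=0.01 * scale)
                _, res = recover(cfg, seed=seed)
                errors.append(abs(res.params.B_m2 / (-0.025 * B) - 1.0))
            errs.append(np.median(errors))
        assert errs[0] > errs[1] > errs[2]

    def test_delay_shift_invariance(self):
        cfg = small_config(tk.water_fixture, seed=9)
        ds, res = recover(cfg, seed=1)
        shift = 2.0
        pulse2 = tk.FieldTrace(ds.pulse.t + shift, ds.pulse.E)
        data2 = PhaseTrace(ds.noisy.t + shift, ds.noisy.phi,
                           sigma=ds.noisy.sigma)
        res2 = tk.KerrModel(data2, pulse2, ds.stack, kind="polar",
                            n_z=cfg.n_z).fit(seed=1)
        assert res2.params.B_m2 == pytest.approx(res.params.B_m2, rel=1e-6)
        assert res2.params.tau2 == pytest.approx(res.params.tau2, rel=1e-6)

    def test_d2o_relaxation_slower_than_h2o(self):
        taus = {}
        for fixture, key in ((tk.water_fixture, "h2o"),
                             (tk.d2o_fixture, "d2o")):
            vals = []
            for seed in (1, 2, 3):
                cfg = small_config(fixture, seed=seed)
                _, res = recover(cfg, seed=seed)
                vals.append(res.params.tau2)
            taus[key] = np.median(vals)
        assert taus["d2o"] / taus["h2o"] == pytest.approx(1.36 / 1.1,
                                                          rel=0.05)

    def test_summary_mentions_all_parameters(self, water_dataset):
        ds = water_dataset
        res = tk.fit_trace(ds.noisy, ds.pulse, ds.stack, seed=7)
        s = res.summary()
        for token in ("B_e", "B_m2", "tau2", "residual rms"):
            assert token in s


class TestElectronicBound:
    def test_bound_shrinks_with_noise(self):
        """With B_e = 0 in truth, the |B_e| bound is finite at small noise
        and shrinks as the noise goes to zero."""
        bounds = []
        for noise in (0.005, 0.002, 0.001):
            cfg = small_config(tk.water_fixture, seed=2).replace(
                jitter=0.0, noise_mrad=noise,
                kerr=tk.water_fixture().kerr.replace(B_e=0.0))
            ds, res = recover(cfg, seed=2)
            bounds.append(res.bound_electronic())
        assert np.all(np.isfinite(bounds))
        assert bounds[0] > bounds[1] > bounds[2] >= 0

    def test_misspecified_zero_be_raises_rms(self):
        cfg = small_config(tk.water_fixture, seed=4).replace(
            jitter=0.0, noise_mrad=0.001,
            kerr=tk.water_fixture().kerr.replace(B_e=0.05 * B))
        ds, res = recover(cfg, seed=4)
        rms_fixed0 = res.model._refit_fixed_be(0.0, res.x[1:].copy())
        assert rms_fixed0 > 2.0 * res.residual_rms * 1e-3


class TestTemperature:
    def make_series(self, jitter=0.0, noise=0.0, seed=0, be=None):
        cfg = small_config(tk.water_temperature_fixture, seed=seed).replace(
            jitter=jitter, noise_mrad=noise)
        if be is not None:
            cfg = cfg.replace(kerr=cfg.kerr.replace(B_e=be, B_m2=0.0))
        ds = tk.generate_experiment(cfg)
        return ds

    def test_requires_multiple_temperatures(self):
        tr = PhaseTrace(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            temperature_decomposition([tr], [296.0])

    def test_electronic_series_has_flat_derivative(self):
        ds = self.make_series(noise=0.001, be=0.01 * B)
        temps = [r.temperature for r in ds.records]
        dec = temperature_decomposition([r.noisy for r in ds.records], temps)
        assert np.max(np.abs(dec.deriv)) < 4 * np.max(dec.stderr)

    def test_orientation_scaling_derivative(self):
        """(T_ref/T)^2 scaling: -dphi/dT at 296 K = 2 phi_m / 296."""
        ds = self.make_series()
        temps = [r.temperature for r in ds.records]
        dec = temperature_decomposition([r.clean for r in ds.records], temps,
                                        degree=2, T_eval=296.0)
        phi_m = ds.records[0].clean.phi  # molecular-only fixture (B_e small)
        # subtract the tiny T-independent electronic part
        cfg = ds.config
        fwd = tk.forward_phase_model(cfg.kerr.replace(B_m2=0.0), ds.pulse,
                                     ds.stack, n_z=cfg.n_z)
        phi_m = phi_m - fwd.total.phi
        expected = 2.0 * phi_m / 296.0
        k = np.argmax(np.abs(expected))
        assert dec.deriv[k] == pytest.approx(expected[k], rel=0.03)

    def test_mixed_series_correlates_with_molecular_trace(self):
        # temperature sweeps are heavily averaged in practice: the
        # per-trace noise of the series is well below a single sweep's
        ds = self.make_series(jitter=0.001, noise=0.0002, seed=6)
        temps = [r.temperature for r in ds.records]
        dec = temperature_decomposition([r.noisy for r in ds.records], temps)
        cfg = ds.config
        fwd = tk.forward_phase_model(cfg.kerr.replace(B_e=0.0), ds.pulse,
                                     ds.stack, n_z=cfg.n_z)
        r = np.corrcoef(dec.deriv, fwd.molecular.phi)[0, 1]
        assert r > 0.99


class TestConcentrationTrend:
    def test_exact_line(self):
        c = np.array([0.0, 1.0, 3.0, 5.0])
        res = concentration_trend(c, -0.02e-14 - 0.008e-14 * c)
        assert res.slope == pytest.approx(-0.008e-14)
        assert np.max(np.abs(res.residuals)) < 1e-22

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            concentration_trend([1.0, 2.0], [0.0, 1.0])

    def test_tabulated_values_against_normal_equations(self):
        c = np.array([0.0, 1.0, 3.0, 5.0, 9.5])
        y = np.array([-0.025, -0.027, -0.043, -0.071, -0.102]) * B
        res = concentration_trend(c, y)
        # independent oracle: normal equations by hand
        n = c.size
        slope_hand = ((n * np.sum(c * y) - np.sum(c) * np.sum(y))
                      / (n * np.sum(c**2) - np.sum(c) ** 2))
        assert res.slope == pytest.approx(slope_hand, rel=1e-12)
        assert res.slope == pytest.approx(-0.0086 * B, rel=0.02)
        assert res.r_squared > 0.98

    def test_nai_series_recovery_and_tau_stability(self):
        """B_m2 grows linearly in magnitude with NaI molarity while the
        relaxation time stays within 10% across the series."""
        med_b = []
        med_tau = []
        mols = []
        for i, base in enumerate(tk.nai_series_fixture()):
            bs, taus = [], []
            for seed in range(3):
                cfg = base.replace(seed=base.seed + 7 * seed)
                _, res = recover(cfg, seed=seed)
                bs.append(res.params.B_m2)
                taus.append(res.params.tau2)
            med_b.append(np.median(bs))
            med_tau.append(np.median(taus))
            mols.append(base.molarity)
        trend = concentration_trend(mols, med_b)
        assert trend.slope < 0  # anisotropy grows with NaI concentration
        taus = np.asarray(med_tau)
        assert np.all(np.abs(taus - taus.mean()) / taus.mean() < 0.10)
        assert med_b[-1] == pytest.approx(-0.102 * B, rel=0.05)
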