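# thzkerr

Forward modelling and decomposition of terahertz-induced Kerr effect
(TKE) traces in polar liquids.

## The problem

An intense single-cycle THz pulse (peak field ~510 kV/cm, 0.25 THz centre
frequency) propagating through a thin liquid sheet induces a transient
birefringence Δn = n∥ − n⊥ that an 800 nm probe reads out as a phase
shift Δφ(t) versus pump-probe delay.  Unlike an optical pump, a THz field
is slow enough to couple to the *permanent* dipole moment μ of the
molecules and transiently **orient** them — not merely align them — so
the sign of the molecular Kerr response reveals the sign of the molecular
polarizability anisotropy Δα = α∥ − α⊥.  For liquid water this sign is
the quantity of interest: a negative molecular response implies Δα < 0,
i.e. the polarizability of a water molecule is *smaller* along its dipole
than perpendicular to it.

This package provides everything needed to run that analysis on synthetic
(or user-supplied) data:

- **materials** — multi-Debye dielectric models ε(ω) = ε∞ + Σ Δε/(1 − iωτ)
  for the studied liquids and the silica cuvette, plus a THz time-domain
  spectroscopy (TDS) transfer-function forward model and its numerical
  inversion;
- **pulse** — zero-area single-cycle waveform synthesis and spectral
  utilities;
- **propagation** — frequency-domain propagation of the pump through the
  window/liquid/window stack (Fresnel interfaces, complex propagation
  phase), and the probe phase integral
  Δφ(t_d) = (2π/λ) ∫₀ᴸ Δn(z, t_d + n_g z/c) dz with group-velocity
  walk-off;
- **response** — the Kerr response model: an instantaneous electronic
  term Δn_e = λ B_e E², and a retarded molecular term built from
  overdamped rotational Langevin dynamics with an alignment coefficient
  B_m⁽¹⁾ ∝ Δα² (always positive) and an orientation coefficient
  B_m⁽²⁾ ∝ μ²Δα (carries the sign of Δα), with exponential memory
  kernels of times τ₁ = τ_D and τ₂ = τ_D/3; plus the molar molecular
  Kerr constant K⁽ᵐ⁾ = N_A · 6 n V_m λ / ((n²+2)²(ε+2)²) · B_m⁽²⁾;
- **fitting** — statsmodels-style `KerrModel.fit()` →
  `KerrFitResults`: trust-region least squares over (B_e, B_m⁽²⁾, τ₂)
  (or B_m⁽¹⁾ for nonpolar liquids), the residual-doubling bound on
  |B_e|, temperature-derivative isolation of the molecular trace
  (−dΔφ/dT ∝ Δφ_m), and concentration trends for salt series;
- **rotor** — an overdamped rotational Brownian-dynamics ensemble of
  dipolar, anisotropically polarizable rotors producing ⟨cos θ⟩ and
  ⟨cos²θ⟩ − 1/3, the desk-scale surrogate for molecular dynamics;
- **synthetic** — complete synthetic experiments (forward model +
  pulse-to-pulse jitter + detection noise) with fixtures preloading the
  tabulated coefficients of water, heavy water, NaI solutions, alcohols
  and nonpolar reference liquids.

## Worked example

```python
import thzkerr as tk

cfg = tk.water_fixture(seed=7)            # 0.2 mm water, 1.2 mm silica windows
ds = tk.generate_experiment(cfg)          # noisy + clean phase traces
res = tk.KerrModel(ds.noisy, ds.pulse, ds.stack, kind="polar").fit(seed=7)
print(res.summary())
K = tk.molecular_kerr_constant(tk.get_material("water"), res.params.B_m2)
print(f"K^(m) = {K:.3g} cm^5/V^2 per mole")
```

prints

```
Kerr trace decomposition
========================
model kind      : polar
liquid          : water
n obs           : 1706
residual rms    : 0.00993 mrad
converged       : True (2)

parameter         estimate     std err  unit
B_e                0.00192     0.00094  1e-14 m/V^2
B_m2              -0.02511     0.00094  1e-14 m/V^2
tau2               1.08627     0.08050  ps
B_m1               0.00000     (fixed)  1e-14 m/V^2
tau1               0.00000     (fixed)  ps

K^(m) = -1.85e+05 cm^5/V^2 per mole
```

The fit recovers the generating parameters of the fixture (orientation
coefficient −0.025×10⁻¹⁴ m/V², relaxation time 1.1 ps) from a trace with
1% pulse-amplitude jitter and 0.01 mrad additive noise; the negative
B_m⁽²⁾ — and hence the negative molecular Kerr constant — is the
signature of Δα < 0.

A command-line interface mirrors the library
(`thzkerr simulate | fit | rotor | kerrconst | tds-extract | smooth`);
all file formats are delimited text with provenance headers.

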