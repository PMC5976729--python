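# Methods

## Response model

The field-induced birefringence of the liquid is the sum of an
instantaneous electronic contribution and a retarded molecular
contribution:

    dn_e(z,t) = lambda * B_e * E^2(z,t)

    dn_m(z,t) = lambda * (T_ref/T)   * B_m1 * [K2 * E^2](z,t)
              + lambda * (T_ref/T)^2 * B_m2 * [K2 * (E . (K1 * E))](z,t)

with normalised causal kernels `K_i(s) = exp(-s/tau_i)/tau_i` and `*`
causal convolution in time at fixed depth z.  The molecular part follows
from overdamped rotational Langevin dynamics of a dipolar, anisotropically
polarizable molecule in the dilute limit: the first (alignment) term
scales with the square of the polarizability anisotropy and is
non-negative; the second (orientation) term scales with `mu^2 *
delta_alpha` and carries the sign of the anisotropy.  For isotropic
rotational diffusion with rate `D_r` the kernel times are the first- and
second-rank relaxation times, `tau_1 = 1/(2 D_r)` (the Debye dielectric
time) and `tau_2 = 1/(6 D_r) = tau_1/3`.

Two modelling conventions deserve explanation:

- **Temperature prefactors.**  The Langevin derivation produces beta and
  beta^2 thermal prefactors on the two molecular terms.  We fold them
  into the coefficients as `(T_ref/T)^k`, k = 1 (alignment) and 2
  (orientation), with `T_ref = 296 K`, so that `B_m1`/`B_m2` carry the
  same m/V^2 unit as `B_e`, tabulated coefficient values apply directly
  at the reference temperature, and the thermal scaling used by the
  temperature-decomposition analysis is preserved.
- **Sign-of-anisotropy observable.**  For any free-space pulse the field
  integral vanishes, so the time-integrated orientation response always
  carries the sign of `B_m2` regardless of the waveform.  This is the
  property that makes a single-cycle THz pump sensitive to the sign of
  `delta_alpha`; it is enforced as a property test over random zero-area
  pulses.
- **tau_1 handling.**  For water the fit constrains `tau_1` far below
  `tau_2`; the default polar model therefore uses the `tau_1 -> 0` delta
  limit, in which both molecular terms share one functional form.  A
  `tied` (`tau_1 = 3 tau_2`) and a fixed-value policy are available.
  Values of `tau_1` below the grid step are switched to the analytic
  delta limit automatically (logged).

The molar molecular Kerr constant is

    K^(m) = N_A * 6 n V_m lambda / ((n^2+2)^2 (eps+2)^2) * B_m2

with `n` the probe-wavelength refractive index, `eps` the square of the
real THz-band index at the pump band (0.37 THz by default), and `V_m`
the molar volume in cm^3/mol; the Avogadro factor puts the constant on
the conventional per-mole cm^5/V^2 scale.

## Propagation and probing

The pump spectrum (e^{-i omega t} convention; absorption means
`Im eps >= 0`) is multiplied per frequency by the Fresnel transmissions
of every interface up to the liquid entrance and by `exp(i n(w) w z / c)`
inside each layer — first pass only: the etalon echoes of the 1.2 mm
windows arrive far outside the 10-20 ps analysis window (an optional echo
order is out of scope; the default is logged in every output header).
The bulk group delay of the windows is removed so t = 0 stays at the pump
peak at the liquid entrance.

The probe travels at its own group velocity, so the phase integral samples
the birefringence along a tilted path:

    dphi(t_d) = (2 pi / lambda) int_0^L dn(z, t_d + n_g z / c) dz

evaluated as a trapezoid in z (64 points by default over the liquid;
convergence-tested: halving the z and t steps changes the water trace by
< 0.5%) with linear interpolation in t.  The probe group index defaults
to the 800 nm refractive index of the liquid (dispersion at 800 nm is
small); it is a per-material field.  Walk-off over 0.2 mm of water smears
an instantaneous response over ~0.77 ps, which is why the decomposition
requires the full forward model rather than a pointwise fit.

## Numerical evaluation of the response integrals

The exponential-kernel convolutions are evaluated by a first-order IIR
recursion (via `scipy.signal.lfilter`) whose coefficients are chosen so
that the recursion reproduces the trapezoid quadrature of the convolution
integral *exactly* on a uniform grid.  A brute-force O(n^2) double
quadrature of the nested integrals serves as the independent oracle; the
two agree to rounding error (tested at 1e-8).  The trapezoid
discretization itself converges as O(dt^2); the default 0.02 ps step puts
the DC steady-state error below 1e-4.

## Fitting

`KerrModel` follows the statsmodels convention: the model object is
built from the data (phase trace, pump waveform, layer stack) and caches
the propagation — which is independent of the Kerr coefficients — once;
`fit()` returns a results object with estimates, Gauss-Newton standard
errors, residual rms, component traces and a `summary()` table.

- Free parameters: `(B_e, B_m2, tau2)` for polar liquids (`B_m1 = 0`:
  the orientation term dominates the alignment term by orders of
  magnitude), `(B_e, B_m1, tau2)` for nonpolar liquids.
- Optimizer: scipy trust-region-reflective least squares with numerical
  Jacobians, parameters scaled to (1e-14 m/V^2, ps).  The model is
  linear in the coefficients at fixed `tau2`, so each of the three
  seeded multi-starts solves the linear subproblem on a tau2 grid point
  before refinement; the best solution wins.
- Weighting: inverse-variance when the trace carries per-point sigma,
  else uniform.
- `|B_e|` bound: scan `|B_e|` upward from zero on a geometric grid,
  refitting the remaining free parameters at each fixed value, and
  bisect to the smallest value at which the residual rms doubles.  On
  *model-generated* data at the standard noise level this bound can be
  unbounded within the scan range (reported as such): in the tau2 -> 0
  limit the orientation kernel collapses to a delta and the molecular
  term can mimic the electronic one, a degeneracy that real traces break
  through model mismatch during the field overlap.  At small noise the
  bound is finite and shrinks proportionally with the noise (tested).
- Temperature decomposition: per-delay polynomial regression of phi
  against T; the negated derivative (at a chosen evaluation temperature)
  isolates the molecular trace, since the electronic response is
  temperature-independent.  Linear regression is used rather than
  two-point differences for noise robustness.

## Rotor simulator

The Brownian ensemble integrates `N` unit dipole axes with an
Euler-Maruyama scheme: deterministic angular velocity `beta D_r` times
the torque `mu (u x E) + delta_alpha (u.E)(u x E)`, plus an isotropic
tangential Gaussian kick of total variance `4 D_r dt`, followed by
renormalisation.  The stability bound `dt * D_r < 0.05` keeps the scheme
in the small-angle regime; at `dt * D_r = 0.005` the residual bias in
the relaxation rates is at the percent level and cancels almost entirely
in the tau1/tau2 ratio.  Relaxation times are estimated from field-free
decay of a weakly oriented and aligned start (`p(c) ~ exp(a c + b c^2)`,
a = 0.8, b = 1.0 by default), fitting each moment over ~2.5 of its own
analytic decay time where the signal stands above the Monte-Carlo floor.
An anisotropic-diffusion option accepts user-supplied principal-axis
rates; rotor-rotor correlations are outside the model (dilute limit).

## Synthetic data and what the tests show

The generator runs the forward model for the standard cuvette (two
1.2 mm silica windows, 0.2 mm liquid; 2 mm for CS2) with a 510 kV/cm,
0.25 THz Gaussian-derivative single-cycle pump, then adds the two noise
channels of the measurement: per-delay pulse-to-pulse amplitude jitter
(multiplicative `(1 + g xi)^2` on the phase, since each delay point is
recorded on a different pump shot) and additive white detection noise.
The default calibration — 1% jitter, 0.01 mrad additive — is an invented
but deliberately nontrivial operating point: the additive noise is a
quarter of the water-trace peak.  Temperature-series fixtures use a
lower noise level (0.1% jitter, 0.0002 mrad), reflecting the heavy
averaging such sweeps receive in practice.

The built-in dielectric models are fixtures, not measurements: the water
family uses the literature relaxation-time triple 9.01/1.03/0.085 ps
with amplitudes solved from the tabulated 0.37 THz complex index and
static permittivity; the remaining liquids use a single effective Debye
term solved the same way.  Their low-frequency limits outside the
0.2-2 THz band (notably for the alcohols) are not realistic and are not
used.

Because generator and fit share one forward model, parameter-recovery
tests demonstrate estimator correctness and noise robustness — not the
adequacy of the response model for real liquids, where the dynamics
during field overlap are known to be imperfectly described.  Problem
sizes used throughout (1751-point traces, 64 z-points, 1e5 rotors,
20-seed medians) are chosen as comfortable desk-scale defaults.

## Known limitations

- First-pass propagation only; oblique incidence, focusing and probe
  depletion are not modelled.
- The electro-optic detector response and lock-in demodulation are not
  emulated; the pump waveform is assumed known exactly.
- The microscopic prefactors relating `B_m1`/`B_m2` to `delta_alpha` and
  `mu` are not modelled; coefficients are empirical.
- Inertial (non-overdamped) rotational dynamics and collective modes are
  out of scope.
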