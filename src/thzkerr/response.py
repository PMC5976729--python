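"""The Kerr response model: electronic and molecular birefringence and the
molecular Kerr constant.

The field-induced birefringence of a liquid is split into a memoryless
electronic part and a retarded molecular part derived from overdamped
rotational Langevin dynamics:

    dn_e(z,t) = lambda * B_e * E^2(z,t)

    dn_m(z,t) = lambda * (T_ref/T)   * B_m1 * [K2 * E^2](t)
              + lambda * (T_ref/T)^2 * B_m2 * [K2 * (E . (K1 * E))](t)

with normalised causal kernels ``K_i(s) = exp(-s/tau_i)/tau_i`` (s >= 0)
and ``*`` denoting causal convolution at fixed z.  The first (alignment)
term scales with the square of the polarizability anisotropy and is
always positive; the second (orientation) term scales with ``mu^2 *
delta_alpha`` and carries the sign of the anisotropy — for a zero-area
free-space pulse its time average always has the sign of ``B_m2``, which
is what makes the sign of ``delta_alpha`` observable.  The temperature
factors ``(T_ref/T)^k`` preserve the beta / beta^2 scaling of the two
Langevin terms while keeping the coefficients in the same m/V^2 unit as
``B_e``; ``T_ref = 296 K`` is the temperature at which tabulated
coefficients apply.

In the ``tau1 -> 0`` limit the inner kernel collapses to a delta and both
molecular terms share one functional form; this limit is used for water,
where the fit constrains ``tau1 < tau2 / 10``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
import numpy as np
from scipy.signal import lfilter

from .constants import N_A, T_REF
from .materials import Material, complex_refractive_index
from .propagation import FieldMap, LayerStack, PhaseTrace, field_in_liquid, probe_phase
from .pulse import FieldTrace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KerrParameters:
    """Coefficient set of the Kerr response model.

    ``B_e``, ``B_m1`` (alignment) and ``B_m2`` (orientation) in m/V^2 (the
    tabulated scale is 1e-14 m/V^2); relaxation times in ps; ``T`` the
    sample temperature and ``T_ref`` the reference temperature at which
    the coefficients are defined.
    """

    B_e: float = 0.0
    B_m1: float = 0.0
    B_m2: float = 0.0
    tau1: float = 0.0
    tau2: float = 1.0
    T: float = T_REF
    T_ref: float = T_REF
    lambda_probe: float = 800e-9

    def __post_init__(self) -> None:
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")
        if self.tau1 < 0:
            raise ValueError("tau1 must be >= 0")
        if self.T <= 0 or self.T_ref <= 0:
            raise ValueError("temperatures must be positive")
        if self.B_m1 < 0:
            raise ValueError("alignment coefficient B_m1 must be >= 0")
        if self.lambda_probe <= 0:
            raise ValueError("lambda_probe must be positive")

    def replace(self, **kw) -> "KerrParameters":
        return replace(self, **kw)


def electronic_birefringence(params: KerrParameters, E):
    """Instantaneous electronic birefringence ``lambda * B_e * E^2``.

    Memoryless and temperature independent; ``E`` may be any array."""
    return params.lambda_probe * params.B_e * np.asarray(E, dtype=float) ** 2


def exponential_filter(x, tau: float, dt: float, axis: int = -1):
    """Causal convolution with the normalised kernel ``exp(-s/tau)/tau``.

    Implemented as the recursion

        y_n = a * y_{n-1} + (dt / 2 tau) * (x_n + a * x_{n-1}),  a = e^{-dt/tau}

    which reproduces the trapezoid quadrature of the convolution integral
    exactly (so the fast path agrees with the brute-force oracle to
    rounding error), at IIR-filter cost via ``scipy.signal.lfilter``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(x, dtype=float)
    a = np.exp(-dt / tau)
    g = dt / (2.0 * tau)
    # initial filter state chosen so y_0 = 0: the trapezoid over a
    # zero-width interval vanishes
    x0 = np.take(x, 0, axis=axis)
    zi = np.expand_dims(-g * x0, axis=axis if axis >= 0 else x.ndim + axis)
    y, _ = lfilter([g, a * g], [1.0, -a], x, axis=axis, zi=zi)
    return y


def _inner_field(params: KerrParameters, E, dt: float, axis: int = -1):
    """E convolved with K1, or E itself in the delta limit tau1 -> 0."""
    if params.tau1 == 0.0:
        return np.asarray(E, dtype=float)
    if params.tau1 < dt:
        log.info("tau1 = %.3g ps below grid step %.3g ps: using the "
                 "analytic delta limit", params.tau1, dt)
        return np.asarray(E, dtype=float)
    return exponential_filter(E, params.tau1, dt, axis=axis)


def molecular_birefringence(params: KerrParameters, E, dt: float,
                            axis: int = -1):
    """Retarded molecular birefringence (alignment + orientation terms).

    ``E`` is the field at one z (1-d) or a full ``(n_z, n_t)`` map with
    time along ``axis``; the grid must be uniform with step ``dt``.
    """
    E = np.asarray(E, dtype=float)
    r = params.T_ref / params.T
    lam = params.lambda_probe
    out = np.zeros_like(E)
    if params.B_m1 != 0.0:
        out += lam * r * params.B_m1 * exponential_filter(E**2, params.tau2,
                                                          dt, axis=axis)
    if params.B_m2 != 0.0:
        inner = _inner_field(params, E, dt, axis=axis)
        out += lam * r**2 * params.B_m2 * exponential_filter(E * inner,
                                                             params.tau2,
                                                             dt, axis=axis)
    return out


def molecular_birefringence_oracle(params: KerrParameters, E, dt: float):
    """Direct trapezoid quadrature of the nested response integrals.

    Reference implementation for tests: O(n^2), 1-d fields of at most
    ~1e3 samples.  Mirrors the same tau1 delta-limit switch as the fast
    path.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 1 or E.size > 2000:
        raise ValueError("oracle accepts 1-d fields of <= 2000 samples")
    n = E.size
    t = dt * np.arange(n)
    r = params.T_ref / params.T
    lam = params.lambda_probe

    def causal_trapezoid(f, tau):
        # y_n = trapezoid_{j<=n} f_j exp(-(t_n-t_j)/tau)/tau
        y = np.empty(n)
        for i in range(n):
            kern = np.exp(-(t[i] - t[: i + 1]) / tau) / tau
            y[i] = np.trapezoid(f[: i + 1] * kern, dx=dt) if i else 0.0
        return y

    out = np.zeros(n)
    if params.B_m1 != 0.0:
        out += lam * r * params.B_m1 * causal_trapezoid(E**2, params.tau2)
    if params.B_m2 != 0.0:
        if params.tau1 < dt:
            inner = E.copy()
        else:
            inner = causal_trapezoid(E, params.tau1)
        out += lam * r**2 * params.B_m2 * causal_trapezoid(E * inner,
                                                           params.tau2)
    return out


@dataclass
class ForwardPhase:
    """Output of the composed forward model: total and component traces."""

    total: PhaseTrace
    electronic: PhaseTrace
    molecular: PhaseTrace
    field_map: FieldMap


def forward_phase_model(params: KerrParameters, pulse: FieldTrace,
                        stack: LayerStack, n_z: int = 64,
                        field_map: FieldMap | None = None,
                        delays=None) -> ForwardPhase:
    """Pulse -> propagation -> birefringence -> probe phase, with the
    electronic and molecular contributions returned separately.

    ``field_map`` may be passed in to reuse a previously computed
    propagation (it does not depend on the Kerr coefficients).
    """
    if field_map is None:
        field_map = field_in_liquid(pulse, stack, n_z=n_z)
    dt = float(field_map.t[1] - field_map.t[0])
    dn_e = electronic_birefringence(params, field_map.E)
    dn_m = molecular_birefringence(params, field_map.E, dt, axis=1)
    phi_e = probe_phase(dn_e, stack, params.lambda_probe,
                        t=field_map.t, z=field_map.z, delays=delays)
    phi_m = probe_phase(dn_m, stack, params.lambda_probe,
                        t=field_map.t, z=field_map.z, delays=delays)
    total = PhaseTrace(phi_e.t.copy(), phi_e.phi + phi_m.phi, meta=phi_e.meta)
    return ForwardPhase(total, phi_e, phi_m, field_map)


def molecular_kerr_constant(material: Material, B_m2: float,
                            lambda_probe: float = 800e-9,
                            pump_freq_thz: float = 0.37) -> float:
    """Molar molecular Kerr constant, cm^5/V^2 per mole.

        K^(m) = N_A * 6 n V_m lambda / ((n^2+2)^2 (eps+2)^2) * B_m2

    with ``n`` the probe refractive index, ``eps`` the square of the real
    THz-band refractive index at ``pump_freq_thz`` and ``V_m`` the molar
    volume.  The Avogadro factor expresses the constant on the tabulated
    per-mole scale.  Carries the sign of ``B_m2``.
    """
    if material.molar_volume is None:
        raise ValueError(f"material {material.name!r} has no molar volume")
    n = material.n_probe
    n_thz = float(np.real(complex_refractive_index(material, pump_freq_thz)))
    eps = n_thz**2
    lam_cm = lambda_probe * 100.0
    b_cm = B_m2 * 100.0  # m/V^2 -> cm/V^2
    return N_A * 6.0 * n * material.molar_volume * lam_cm * b_cm / (
        (n**2 + 2.0) ** 2 * (eps + 2.0) ** 2
    )
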