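"""Frequency-domain propagation of the pump through the cuvette and the
probe phase-shift integral with group-velocity walk-off.

The pump spectrum is multiplied, per frequency, by the Fresnel
transmissions of every interface up to the liquid entrance and by the
propagation phase ``exp(i n(w) w z / c)`` inside each layer (first pass
only: etalon echoes of the thick windows fall far outside the analysis
window).  The probe samples the induced birefringence along its own path,

    dphi(t_d) = (2 pi / lambda) * int_0^L dn(z, t_d + n_g z / c) dz,

where ``n_g`` is the probe group index and ``t_d`` the pump-probe delay
referenced to the pump peak at the liquid entrance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
import numpy as np

from .constants import C_M_PER_PS
from .materials import Material, complex_refractive_index, fresnel_transmission
from .pulse import FieldTrace, center_frequency

__all__ = [
    "LayerStack", "FieldMap", "PhaseTrace", "fresnel_transmission",
    "field_in_liquid", "probe_phase", "cuvette_stack",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers ``(material, thickness_m)`` with one designated liquid."""

    layers: tuple[tuple[Material, float], ...]
    liquid_index: int

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not 0 <= self.liquid_index < len(layers):
            raise ValueError("liquid_index out of range")
        for _, d in layers:
            if d < 0:
                raise ValueError("layer thickness must be >= 0")

    @property
    def liquid(self) -> Material:
        return self.layers[self.liquid_index][0]

    @property
    def liquid_thickness(self) -> float:
        return self.layers[self.liquid_index][1]

    @property
    def pre_liquid(self):
        return self.layers[: self.liquid_index]


def cuvette_stack(liquid: Material, liquid_thickness: float = 0.2e-3,
                  window: Material | None = None,
                  window_thickness: float = 1.2e-3) -> LayerStack:
    """Window / liquid / window stack of the standard cuvette geometry."""
    if window is None:
        from .materials import silica
        window = silica
    return LayerStack(
        ((window, window_thickness), (liquid, liquid_thickness),
         (window, window_thickness)),
        liquid_index=1,
    )


@dataclass
class FieldMap:
    """Pump field ``E(z, t)`` on a grid inside the liquid layer.

    ``z`` in metres from the liquid entrance, ``t`` in ps (t = 0 is the
    pump peak at the liquid entrance when re-timing is enabled), ``E`` of
    shape ``(n_z, n_t)`` in V/m.
    """

    z: np.ndarray
    t: np.ndarray
    E: np.ndarray
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (self.z.size, self.t.size):
            raise ValueError("E must have shape (n_z, n_t)")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("non-finite field values")


@dataclass
class PhaseTrace:
    """Probe phase shift vs pump-probe delay; ``phi`` in radians."""

    t: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.t.shape != self.phi.shape or self.t.ndim != 1:
            raise ValueError("t and phi must be 1-d arrays of equal length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.t.shape:
                raise ValueError("sigma must match t")

    @property
    def phi_mrad(self) -> np.ndarray:
        return self.phi * 1e3


def field_in_liquid(pulse: FieldTrace, stack: LayerStack, n_z: int = 64,
                    retime: bool = True) -> FieldMap:
    """Propagate the incident pulse to a z-grid inside the liquid layer.

    Per frequency the physical (``e^{-i w t}``) spectrum is multiplied by
    the cumulative interface transmissions up to the liquid entrance and by
    ``exp(i n_liq(w) w z / c)`` within the liquid; the field is then
    transformed back per z.  First-pass only.  With ``retime`` the bulk
    group delay of the pre-liquid layers (evaluated at the pulse centre
    frequency) is removed, so t = 0 stays at the pump peak at the liquid
    entrance.
    """
    n = pulse.t.size
    dt = pulse.dt
    f = np.fft.rfftfreq(n, dt)            # THz
    w = 2.0 * np.pi * f                   # rad/ps
    # physical spectrum under e^{-i w t}: conjugate of numpy's convention
    S = np.conj(np.fft.rfft(pulse.E))

    # aliasing check: spectral energy above half-Nyquist
    mag2 = np.abs(S) ** 2
    hi = mag2[f > 0.25 / dt].sum()
    if hi > 0.01 * mag2.sum():
        log.warning("more than 1%% of pulse energy above Nyquist/2; "
                    "time step %.3g ps may be too coarse", dt)

    n_prev = np.ones_like(f, dtype=complex)  # air in front
    acc = np.ones_like(f, dtype=complex)
    delay = 0.0
    f_ref = center_frequency(pulse)
    for mat, d in stack.pre_liquid:
        n_lay = complex_refractive_index(mat, f)
        acc = acc * fresnel_transmission(n_prev, n_lay)
        acc = acc * np.exp(1j * n_lay * w * d / C_M_PER_PS)
        delay += float(np.real(complex_refractive_index(mat, f_ref))) * d / C_M_PER_PS
        n_prev = n_lay
    n_liq = complex_refractive_index(stack.liquid, f)
    acc = acc * fresnel_transmission(n_prev, n_liq)
    if retime:
        acc = acc * np.exp(-1j * w * delay)

    z = np.linspace(0.0, stack.liquid_thickness, n_z)
    phase = np.exp(1j * n_liq[None, :] * w[None, :] * z[:, None] / C_M_PER_PS)
    Sz = S[None, :] * acc[None, :] * phase
    E = np.fft.irfft(np.conj(Sz), n, axis=1)
    return FieldMap(z, pulse.t.copy(), E,
                    {"liquid": stack.liquid.name, "retimed": retime,
                     "pre_liquid_delay_ps": delay})


def probe_phase(dn, stack: LayerStack, lambda_probe: float,
                t: np.ndarray | None = None, z: np.ndarray | None = None,
                delays: np.ndarray | None = None) -> PhaseTrace:
    """Probe phase shift from a birefringence map ``dn(z, t)``.

    ``dn`` may be a FieldMap-shaped object (``.z``, ``.t``, array in ``.E``)
    or a plain array with explicit ``t`` and ``z`` grids.  The integral is
    a trapezoid in z with linear interpolation in t at the walked-off
    sample times ``t_d + n_g z / c``.  If ``delays`` is omitted, the
    largest delay grid for which all sample times stay inside ``t`` is
    used; explicit delays outside that range raise an error naming the
    required padding.
    """
    if hasattr(dn, "z") and hasattr(dn, "t"):
        z = dn.z
        t = dn.t
        dn = dn.E
    dn = np.asarray(dn, dtype=float)
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    n_g = stack.liquid.n_group_probe
    shifts = n_g * z / C_M_PER_PS  # ps
    max_shift = float(shifts[-1])
    if delays is None:
        delays = t[t <= t[-1] - max_shift + 1e-12]
        if delays.size == 0:
            raise ValueError(
                "walk-off exceeds the time grid span; pad the time grid by "
                f"at least {max_shift:.2f} ps")
    else:
        delays = np.asarray(delays, dtype=float)
        if delays[0] < t[0] or delays[-1] + max_shift > t[-1] + 1e-12:
            raise ValueError(
                "requested delays push walked-off sampling outside the time "
                f"grid; pad the grid to cover "
                f"[{delays[0]:.2f}, {delays[-1] + max_shift:.2f}] ps")
    sampled = np.empty((z.size, delays.size))
    for i, s in enumerate(shifts):
        sampled[i] = np.interp(delays + s, t, dn[i])
    phi = (2.0 * np.pi / lambda_probe) * np.trapezoid(sampled, z, axis=0)
    return PhaseTrace(delays, phi,
                      meta={"delay_origin": "pump peak at liquid entrance",
                            "lambda_probe_m": lambda_probe})
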