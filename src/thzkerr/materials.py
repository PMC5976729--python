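"""Dielectric and optical property models for liquids and cuvette windows.

The THz-band response of every liquid handled here is described by a
multi-Debye dielectric function

    eps(f) = eps_inf + sum_k  delta_eps_k / (1 - i * 2*pi*f * tau_k)

with the time convention ``e^{-i omega t}``, so that absorption means
``Im eps >= 0`` and ``Im n >= 0``.  The same convention is shared by the
propagation and spectroscopy code.

The shipped built-in materials are *fixtures*, not measurements: the water
family uses the literature relaxation times 9.01 / 1.03 / 0.085 ps with
amplitudes solved so that the refractive index at 0.37 THz and the static
permittivity take tabulated values; the remaining liquids use a single
effective Debye term solved the same way.  They are intended to give the
forward model realistic dispersion and loss, not to serve as reference
dielectric data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .constants import C_M_PER_PS


@dataclass(frozen=True)
class DebyeModel:
    """Multi-term Debye relaxation model of a complex permittivity.

    Parameters
    ----------
    eps_inf : float
        High-frequency (electronic) permittivity, dimensionless.
    terms : tuple of (float, float)
        ``(delta_eps, tau_ps)`` pairs; relaxation strengths are
        dimensionless, relaxation times in picoseconds.
    """

    eps_inf: float
    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.eps_inf <= 0:
            raise ValueError("eps_inf must be positive")
        for de, tau in self.terms:
            if tau <= 0:
                raise ValueError(f"relaxation time must be positive, got {tau}")
            if de < 0:
                raise ValueError(f"relaxation strength must be >= 0, got {de}")

    @property
    def eps_static(self) -> float:
        """DC permittivity, ``eps_inf + sum(delta_eps)``."""
        return self.eps_inf + sum(de for de, _ in self.terms)


def evaluate_epsilon(model: DebyeModel, freq_thz):
    """Complex permittivity of a Debye model at ``freq_thz`` (scalar or array).

    Uses the ``e^{-i omega t}`` convention, so ``Im eps >= 0`` for all
    non-negative frequencies.  Negative frequencies are rejected.
    """
    f = np.asarray(freq_thz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    eps = np.full(f.shape, model.eps_inf, dtype=complex)
    for de, tau in model.terms:
        eps += de / (1.0 - 1j * 2.0 * np.pi * f * tau)
    return eps if eps.shape else complex(eps)


@dataclass(frozen=True)
class Material:
    """A liquid or window material: THz dielectric model plus probe optics.

    ``n_probe`` is the refractive index at the 800 nm probe wavelength and
    ``n_group_probe`` the corresponding group index used for pump-probe
    walk-off (defaults to ``n_probe``; dispersion of these liquids at
    800 nm is small).  ``molar_volume`` is in cm^3/mol and is only needed
    to convert a fitted orientation coefficient into a molecular Kerr
    constant.
    """

    name: str
    debye: DebyeModel
    n_probe: float
    n_group_probe: float | None = None
    molar_volume: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_probe < 1:
            raise ValueError("n_probe must be >= 1")
        if self.molar_volume is not None and self.molar_volume <= 0:
            raise ValueError("molar_volume must be positive")
        if self.n_group_probe is None:
            object.__setattr__(self, "n_group_probe", self.n_probe)

    def epsilon(self, freq_thz):
        return evaluate_epsilon(self.debye, freq_thz)


def complex_refractive_index(material, freq_thz):
    """Complex index ``n + i*kappa`` (principal square root of epsilon).

    Accepts a :class:`Material` or a :class:`DebyeModel`.  With the shared
    sign convention both ``n`` and ``kappa`` are non-negative.
    """
    model = material.debye if isinstance(material, Material) else material
    return np.sqrt(evaluate_epsilon(model, freq_thz))


@dataclass
class DielectricTable:
    """Tabulated complex permittivity on a strictly increasing THz grid."""

    freqs: np.ndarray
    eps: np.ndarray
    converged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.eps = np.asarray(self.eps, dtype=complex)
        if self.freqs.ndim != 1 or self.freqs.size != self.eps.size:
            raise ValueError("freqs and eps must be 1-d arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not (np.all(np.isfinite(self.freqs)) and np.all(np.isfinite(self.eps))):
            raise ValueError("non-finite values in dielectric table")
        if self.converged is None:
            self.converged = np.ones(self.freqs.size, dtype=bool)


# --------------------------------------------------------------------------
# THz time-domain spectroscopy forward model and inversion
# --------------------------------------------------------------------------

def _layer_index(layer_material, freq_thz):
    if isinstance(layer_material, (Material, DebyeModel)):
        return complex_refractive_index(layer_material, freq_thz)
    return np.asarray(layer_material, dtype=complex) * np.ones_like(
        np.asarray(freq_thz, dtype=float), dtype=complex
    )


def _stack_transmission(stack, freq_thz):
    """First-pass amplitude transmission through a stack in air, referenced
    to vacuum of the same physical span (factor exp(i (n-1) w d / c) per
    layer), so that two stacks of different total thickness still yield a
    well-defined transfer ratio."""
    f = np.asarray(freq_thz, dtype=float)
    w = 2.0 * np.pi * f
    t = np.ones_like(f, dtype=complex)
    n_prev = np.ones_like(f, dtype=complex)  # air
    for mat, d in stack:
        if d < 0:
            raise ValueError("layer thickness must be >= 0")
        n = _layer_index(mat, f)
        t = t * fresnel_transmission(n_prev, n)
        t = t * np.exp(1j * (n - 1.0) * w * d / C_M_PER_PS)
        n_prev = n
    t = t * fresnel_transmission(n_prev, np.ones_like(f, dtype=complex))
    return t


def fresnel_transmission(n1, n2):
    """Normal-incidence amplitude transmission ``t = 2 n1 / (n1 + n2)``."""
    n1 = np.asarray(n1, dtype=complex)
    n2 = np.asarray(n2, dtype=complex)
    s = n1 + n2
    if np.any(s == 0):
        raise ValueError("degenerate interface: n1 + n2 = 0")
    return 2.0 * n1 / s


def tds_transfer_function(stack_sample, stack_reference, freq_thz):
    """Complex transfer ratio ``H = T_sample / T_reference`` of two stacks.

    Each stack is a sequence of ``(material_or_index, thickness_m)`` layers
    embedded in air; the forward model is first-pass only (no etalon
    echoes).  Identical stacks give ``H == 1`` at every frequency.
    """
    return _stack_transmission(stack_sample, freq_thz) / _stack_transmission(
        stack_reference, freq_thz
    )


def extract_epsilon_from_transfer(
    H,
    freqs,
    stack_sample,
    stack_reference,
    liquid_index: int,
    eps_init=5.0 + 1.0j,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> DielectricTable:
    """Invert measured transfer ratios for the liquid-layer permittivity.

    Per frequency, solves ``tds_transfer_function(eps) == H`` for the
    permittivity of the layer at ``liquid_index`` in ``stack_sample`` by a
    damped Newton iteration on the analytic map ``eps -> H``, initialised
    from the solution at the previous frequency.  Frequencies where the
    iteration does not reach ``|H_model - H| <= tol`` are flagged in the
    returned table's ``converged`` mask rather than failing silently.
    """
    freqs = np.asarray(freqs, dtype=float)
    H = np.asarray(H, dtype=complex)
    if freqs.shape != H.shape:
        raise ValueError("freqs and H must have matching shapes")
    stack_sample = list(stack_sample)
    eps_out = np.empty(freqs.size, dtype=complex)
    ok = np.zeros(freqs.size, dtype=bool)

    def model_H(eps, f):
        stack = list(stack_sample)
        mat, d = stack[liquid_index]
        stack[liquid_index] = (np.sqrt(eps), d)
        return complex(tds_transfer_function(stack, stack_reference, np.array([f]))[0])

    eps = complex(eps_init)
    h_step = 1e-7
    for k, f in enumerate(freqs):
        target = H[k]
        for _ in range(max_iter):
            r = model_H(eps, f) - target
            if abs(r) <= tol:
                ok[k] = True
                break
            d = (model_H(eps + h_step, f) - model_H(eps, f)) / h_step
            if d == 0:
                break
            step = r / d
            # damped update, keep Im eps physical
            lam = 1.0
            for _ in range(20):
                trial = eps - lam * step
                if trial.imag >= 0 and abs(model_H(trial, f) - target) < abs(r):
                    eps = trial
                    break
                lam *= 0.5
            else:
                eps = eps - 1e-3 * step
        eps_out[k] = eps
    return DielectricTable(freqs, eps_out, converged=ok)


# --------------------------------------------------------------------------
# Built-in materials (synthetic parametrizations; see module docstring)
# --------------------------------------------------------------------------

_WATER_TAUS = (9.01, 1.03, 0.085)

_BUILTINS: dict[str, Material] = {}


def _register(mat: Material) -> Material:
    _BUILTINS[mat.name] = mat
    return mat


def _triple(eps_inf, amps, taus=_WATER_TAUS):
    return DebyeModel(eps_inf, tuple(zip(amps, taus)))


vacuum = _register(
    Material("vacuum", DebyeModel(1.0, ()), 1.0, notes="ideal vacuum / air")
)

water = _register(Material(
    "water",
    _triple(2.5, (71.596, 1.967, 2.437)),
    n_probe=1.3282,
    molar_volume=18.07,
    notes="triple-Debye fixture: taus 9.01/1.03/0.085 ps; amplitudes solved "
          "for n(0.37 THz)=2.48+0.92i and eps(0)=78.5",
))

d2o = _register(Material(
    "d2o",
    _triple(2.5, (71.999, 1.517, 2.083), (10.37, 1.2, 0.1)),
    n_probe=1.324,
    molar_volume=18.13,
    notes="triple-Debye fixture for heavy water: n(0.37 THz)=2.34+0.84i",
))

silica = _register(Material(
    "silica",
    DebyeModel(3.70, ((0.1163, 0.1584),)),
    n_probe=1.453,
    notes="fused-silica window fixture: n(0.37 THz)=1.95, low loss",
))

cs2 = _register(Material(
    "cs2",
    DebyeModel(2.60, ((0.2903, 0.0130),)),
    n_probe=1.6058,
    molar_volume=60.6,
    notes="carbon disulfide fixture: n(0.37 THz)=1.70, nearly lossless",
))

benzene = _register(Material(
    "benzene",
    DebyeModel(2.23, ((0.0653, 0.2378),)),
    n_probe=1.489,
    molar_volume=89.4,
    notes="benzene fixture: n(0.37 THz)=1.51",
))

methanol = _register(Material(
    "methanol",
    DebyeModel(2.00, ((3.1270, 0.5875),)),
    n_probe=1.323,
    molar_volume=40.5,
    notes="single effective Debye term fixture: n(0.37 THz)=1.806+0.41i",
))

ethanol = _register(Material(
    "ethanol",
    DebyeModel(1.90, ((0.9619, 0.3051),)),
    n_probe=1.3573,
    molar_volume=58.4,
    notes="single effective Debye term fixture: n(0.37 THz)=1.60+0.14i",
))

propan2ol = _register(Material(
    "2-propanol",
    DebyeModel(1.90, ((0.8743, 0.4163),)),
    n_probe=1.379,
    molar_volume=76.5,
    notes="single effective Debye term fixture: n(0.37 THz)=1.54+0.14i",
))

nai_1m = _register(Material(
    "nai-1m",
    _triple(2.5, (63.558, 5.025, 1.917)),
    n_probe=1.347,
    molar_volume=18.07,
    notes="1 M NaI(aq) fixture: n(0.37 THz)=2.51+1.03i",
))

nai_3m = _register(Material(
    "nai-3m",
    _triple(2.5, (49.333, 8.140, 2.026)),
    n_probe=1.388,
    molar_volume=18.07,
    notes="3 M NaI(aq) fixture: n(0.37 THz)=2.63+1.07i",
))

nai_5m = _register(Material(
    "nai-5m",
    _triple(2.5, (36.760, 10.270, 2.470)),
    n_probe=1.420,
    molar_volume=18.07,
    notes="5 M NaI(aq) fixture: n(0.37 THz)=2.76+1.06i",
))

nai_95m = _register(Material(
    "nai-9.5m",
    _triple(2.5, (29.273, 10.831, 3.396)),
    n_probe=1.475,
    molar_volume=18.07,
    notes="9.5 M NaI(aq) fixture: n(0.37 THz)=2.91+1.01i",
))


def builtin_names() -> list[str]:
    return sorted(_BUILTINS)


def get_material(name: str) -> Material:
    """Look up a built-in material by name (case-insensitive)."""
    key = name.lower()
    aliases = {"h2o": "water", "air": "vacuum", "ipa": "2-propanol",
               "isopropanol": "2-propanol", "fused-silica": "silica"}
    key = aliases.get(key, key)
    if key not in _BUILTINS:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {', '.join(builtin_names())}"
        )
    return _BUILTINS[key]


def scaled_material(mat: Material, debye_scale: float) -> Material:
    """Return a copy with all relaxation strengths scaled by ``debye_scale``
    (a crude hook for temperature dependence of the dielectric function)."""
    terms = tuple((de * debye_scale, tau) for de, tau in mat.debye.terms)
    return replace(mat, debye=DebyeModel(mat.debye.eps_inf, terms))
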