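"""Overdamped rotational Brownian dynamics of polar, anisotropically
polarizable rigid rotors in a time-dependent field.

A desk-scale surrogate for molecular-dynamics simulation of the
orientation mechanism: each rotor is a unit vector ``u`` carrying a
permanent dipole ``mu`` along ``u`` and a polarizability anisotropy
``delta_alpha``; in the overdamped, dilute limit the deterministic
angular velocity is ``beta * D_r`` times the torque

    N = mu (u x E) + delta_alpha (u.E)(u x E),

and the Brownian rotation adds an isotropic tangential displacement of
total variance ``4 D_r dt`` per step (Euler-Maruyama with renormalisation
of ``u``).  Free orientational moments then decay with the classic
eigenvalues ``l(l+1) D_r``: the first-rank moment <cos theta> with
``tau_1 = 1/(2 D_r)`` (the Debye time) and the second-rank excess
``<cos^2 theta> - 1/3`` with ``tau_2 = 1/(6 D_r) = tau_1 / 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
import numpy as np
from scipy.optimize import curve_fit

from .constants import K_B
from .pulse import FieldTrace


@dataclass(frozen=True)
class RotorConfig:
    """Ensemble and integrator settings.

    ``mu`` in C*m, ``delta_alpha`` in C*m^2/V, ``D_r`` in rad^2/ps (scalar
    isotropic, or a 3-tuple of principal-axis rates for the anisotropic
    option), ``dt`` in ps.  The stability bound ``dt * D_r < 0.05`` keeps
    the per-step Brownian rotation in the small-angle regime.
    """

    mu: float = 6.17e-30
    delta_alpha: float = 0.0
    D_r: float | tuple[float, float, float] = 0.1
    T: float = 296.0
    n_rotors: int = 10_000
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.D_r, dtype=float))
        if np.any(rates <= 0):
            raise ValueError("D_r must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt * float(np.max(rates)) >= 0.05:
            raise ValueError("stability bound violated: require dt * D_r < 0.05")
        if self.n_rotors < 1:
            raise ValueError("n_rotors must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (K_B * self.T)

    @property
    def isotropic(self) -> bool:
        return np.ndim(self.D_r) == 0


@dataclass
class RotorObservables:
    """Ensemble orientational moments vs time with standard errors."""

    t: np.ndarray
    mean_cos: np.ndarray
    mean_cos2_excess: np.ndarray
    se_cos: np.ndarray
    se_cos2: np.ndarray
    meta: dict = dfield(default_factory=dict)


def _uniform_sphere(rng, n):
    u = rng.standard_normal((n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def sample_biased_start(rng, n, a: float = 0.0, b: float = 0.0):
    """Sample unit vectors with ``p(cos theta) ~ exp(a c + b c^2)``.

    Rejection sampling; ``a`` biases orientation (first rank), ``b``
    alignment (second rank).  Azimuth is uniform.
    """
    c = np.empty(n)
    filled = 0
    wmax = np.exp(np.max(a * np.array([-1, 1])) + max(b, 0.0))
    while filled < n:
        m = 2 * (n - filled) + 16
        cand = rng.uniform(-1, 1, m)
        acc = rng.uniform(0, wmax, m) < np.exp(a * cand + b * cand**2)
        take = cand[acc][: n - filled]
        c[filled:filled + take.size] = take
        filled += take.size
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - c**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


def simulate_ensemble(config: RotorConfig, field: FieldTrace | None = None,
                      t_max: float | None = None, u0=None,
                      record_every: int = 1, return_state: bool = False):
    """Euler-Maruyama integration of the rotor ensemble.

    The field (V/m) is applied along z; ``field=None`` (or zero) with
    ``t_max`` simulates free relaxation.  The field trace is linearly
    resampled onto the simulation grid when its step differs from
    ``config.dt``.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    if field is not None:
        t = np.arange(field.t[0], field.t[-1] + 0.5 * dt, dt)
        Ez = np.interp(t, field.t, field.E)
    else:
        if t_max is None:
            raise ValueError("need a field or an explicit t_max")
        t = np.arange(0.0, t_max + 0.5 * dt, dt)
        Ez = np.zeros_like(t)

    n = config.n_rotors
    u = _uniform_sphere(rng, n) if u0 is None else np.array(u0, dtype=float)
    rates = np.atleast_1d(np.asarray(config.D_r, dtype=float))
    D_iso = float(rates.mean())
    anisotropic = rates.size == 3 and not np.allclose(rates, rates[0])
    beta = config.beta

    n_rec = (t.size + record_every - 1) // record_every
    mc = np.empty(n_rec)
    mc2 = np.empty(n_rec)
    sc = np.empty(n_rec)
    sc2 = np.empty(n_rec)

    k = 0
    for i, ti in enumerate(t):
        if i % record_every == 0:
            cz = u[:, 2]
            mc[k] = cz.mean()
            mc2[k] = (cz**2).mean() - 1.0 / 3.0
            sc[k] = cz.std(ddof=1) / np.sqrt(n)
            sc2[k] = (cz**2).std(ddof=1) / np.sqrt(n)
            k += 1
        E = Ez[i]
        if E != 0.0:
            udotE = u[:, 2] * E
            # (torque x u) reduces to the transverse field component
            E_perp = -udotE[:, None] * u
            E_perp[:, 2] += E
            drift = (beta * D_iso * dt) * (config.mu
                                           + config.delta_alpha * udotE
                                           )[:, None] * E_perp
            u = u + drift
        if anisotropic:
            # principal-axis rates in the body frame of each rotor: build a
            # tangential kick with per-axis variance 2*D_a*dt projected back
            xi = rng.standard_normal((n, 3)) * np.sqrt(2.0 * rates * dt)
        else:
            xi = rng.standard_normal((n, 3)) * np.sqrt(2.0 * D_iso * dt)
        xi -= np.sum(xi * u, axis=1, keepdims=True) * u
        u = u + xi
        u /= np.linalg.norm(u, axis=1, keepdims=True)

    t_rec = t[::record_every][:n_rec]
    obs = RotorObservables(t_rec, mc, mc2, sc, sc2,
                           {"seed": config.seed, "n_rotors": n,
                            "dt_ps": dt, "D_r": config.D_r})
    return (obs, u) if return_state else obs


def _fit_exponential(t, y, se, tau_guess):
    def f(t, a, tau):
        return a * np.exp(-t / tau)
    p0 = (y[0], tau_guess)
    popt, _ = curve_fit(f, t, y, p0=p0, sigma=np.maximum(se, 1e-12),
                        absolute_sigma=True, maxfev=10_000)
    if popt[1] <= 0:
        raise RuntimeError("exponential fit returned non-positive time")
    return float(popt[1])


def relaxation_times(config: RotorConfig, a: float = 0.8, b: float = 1.0,
                     t_max: float | None = None) -> tuple[float, float]:
    """Free-decay relaxation times of the first- and second-rank moments.

    Starts the ensemble from a weakly oriented and aligned distribution,
    simulates field-free relaxation, and fits single exponentials to
    ``<cos theta>(t)`` and ``<cos^2 theta>(t) - 1/3``.  For isotropic
    rotational diffusion the targets are ``1/(2 D_r)`` and ``1/(6 D_r)``,
    i.e. a ratio of exactly 3 — the relation between the Debye dielectric
    relaxation time and the Kerr-response time ``tau_2 = tau_D / 3``.
    """
    if not config.isotropic:
        raise ValueError("relaxation_times requires isotropic D_r")
    D = float(config.D_r)
    tau1 = 1.0 / (2.0 * D)
    if t_max is None:
        t_max = 2.2 * tau1
    rng = np.random.default_rng(config.seed + 1)
    u0 = sample_biased_start(rng, config.n_rotors, a=a, b=b)
    obs = simulate_ensemble(config, t_max=t_max, u0=u0)
    # fit each moment over ~2.5 of its own decay time, where the signal
    # stands above the Monte-Carlo floor
    m1 = obs.t <= 2.5 * tau1
    m2 = obs.t <= 2.5 * tau1 / 3.0
    try:
        t1 = _fit_exponential(obs.t[m1], obs.mean_cos[m1], obs.se_cos[m1],
                              tau1)
        t2 = _fit_exponential(obs.t[m2], obs.mean_cos2_excess[m2],
                              obs.se_cos2[m2], tau1 / 3.0)
    except Exception as exc:
        raise RuntimeError(f"relaxation-time fit failed: {exc}") from exc
    return t1, t2


def birefringence_proxy(obs: RotorObservables, delta_alpha: float
                        ) -> np.ndarray:
    """Birefringence proxy ``delta_alpha * (<cos^2 theta> - 1/3)``.

    When orientation dominates, the sign of its time average follows the
    sign of ``delta_alpha`` — the observable that fixes the sign of the
    polarizability anisotropy.
    """
    return delta_alpha * obs.mean_cos2_excess
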