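"""Decomposition of measured phase traces into electronic and molecular
contributions by nonlinear least squares.

The model surface follows the statsmodels convention: a :class:`KerrModel`
is built from the data (phase trace, pump waveform, cuvette stack), its
:meth:`~KerrModel.fit` returns a :class:`KerrFitResults` carrying the
estimates, their standard errors, residual diagnostics, the component
traces and a ``summary()`` table.

For polar liquids the free parameters are ``(B_e, B_m2, tau2)`` with the
alignment coefficient fixed to zero (the orientation term dominates by
orders of magnitude); for nonpolar liquids ``(B_e, B_m1, tau2)`` with the
orientation term absent.  The model is linear in the coefficients at fixed
``tau2``, which the initialiser exploits: each start solves the linear
subproblem on a tau2 grid point before the trust-region refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
import numpy as np
from scipy.optimize import least_squares

from .propagation import FieldMap, LayerStack, PhaseTrace, field_in_liquid, probe_phase
from .pulse import FieldTrace
from .response import (KerrParameters, electronic_birefringence,
                       molecular_birefringence)

B_SCALE = 1e-14  # tabulated coefficient unit, m/V^2


@dataclass
class KerrFitResults:
    """Results of a Kerr-trace decomposition.

    ``params`` holds the fitted coefficient set; ``bse`` the standard
    errors of the free parameters (same order as ``free_names``) from the
    Gauss-Newton covariance; traces are on the data delay grid.
    """

    model: "KerrModel"
    params: KerrParameters
    free_names: tuple[str, ...]
    x: np.ndarray                      # free parameters, (1e-14 m/V^2, ps)
    bse: np.ndarray
    residual_rms: float                # mrad
    trace_total: PhaseTrace
    trace_electronic: PhaseTrace
    trace_molecular: PhaseTrace
    converged: bool
    n_iter: int
    message: str
    config: dict = dfield(default_factory=dict)

    @property
    def resid(self) -> np.ndarray:
        return self.model.data.phi - self.trace_total.phi

    def summary(self) -> str:
        lines = [
            "Kerr trace decomposition",
            "========================",
            f"model kind      : {self.model.kind}",
            f"liquid          : {self.model.stack.liquid.name}",
            f"n obs           : {self.model.data.t.size}",
            f"residual rms    : {self.residual_rms:.5f} mrad",
            f"converged       : {self.converged} ({self.message})",
            "",
            f"{'parameter':<12}{'estimate':>14}{'std err':>12}  unit",
        ]
        units = {"B_e": "1e-14 m/V^2", "B_m1": "1e-14 m/V^2",
                 "B_m2": "1e-14 m/V^2", "tau2": "ps", "tau1": "ps"}
        for name, val, se in zip(self.free_names, self.x, self.bse):
            lines.append(f"{name:<12}{val:>14.5f}{se:>12.5f}  {units[name]}")
        fixed = [n for n in ("B_e", "B_m1", "B_m2", "tau1", "tau2")
                 if n not in self.free_names]
        for name in fixed:
            v = getattr(self.params, name)
            if name.startswith("B"):
                v /= B_SCALE
            lines.append(f"{name:<12}{v:>14.5f}{'(fixed)':>12}  {units[name]}")
        return "\n".join(lines)

    def bound_electronic(self, factor: float = 2.0,
                         scan_max: float = 1.0) -> float:
        """Upper bound on |B_e| by the residual-doubling criterion.

        Scans |B_e| upward from zero on a geometric grid, refitting the
        remaining free parameters at each fixed value, and returns the
        smallest |B_e| (m/V^2) at which the residual rms reaches
        ``factor`` times the free-fit minimum, refined by bisection.
        Returns ``inf`` if the rms never doubles below ``scan_max``
        (1e-14 m/V^2 units).
        """
        return self.model._bound_electronic(self, factor, scan_max)


class KerrModel:
    """Forward Kerr model bound to one measured (or synthetic) phase trace.

    Parameters
    ----------
    data : PhaseTrace
        Measured phase shift vs pump-probe delay (radians internally).
    pulse : FieldTrace
        Incident pump waveform from electro-optic sampling.
    stack : LayerStack
        Cuvette geometry; the propagation through it is computed once at
        construction and cached (it does not depend on the coefficients).
    kind : {"polar", "nonpolar"}
        Selects the free molecular coefficient (B_m2 or B_m1).
    tau1_policy : {"zero", "tied", float}
        tau1 = 0 (delta limit, the water default), tau1 = 3 tau2, or a
        fixed value in ps.
    """

    def __init__(self, data: PhaseTrace, pulse: FieldTrace, stack: LayerStack,
                 kind: str = "polar", tau1_policy="zero",
                 lambda_probe: float = 800e-9, weights=None, n_z: int = 64,
                 T: float = 296.0):
        if kind not in ("polar", "nonpolar"):
            raise ValueError("kind must be 'polar' or 'nonpolar'")
        self.data = data
        self.pulse = pulse
        self.stack = stack
        self.kind = kind
        self.tau1_policy = tau1_policy
        self.lambda_probe = lambda_probe
        self.n_z = n_z
        self.T = T
        self.weights = (np.ones_like(data.phi) if weights is None
                        else np.asarray(weights, dtype=float))
        if data.sigma is not None and weights is None:
            self.weights = 1.0 / np.maximum(data.sigma, 1e-30)
        self.field_map: FieldMap = field_in_liquid(pulse, stack, n_z=n_z)
        self._dt = float(self.field_map.t[1] - self.field_map.t[0])
        self._check_delays()

    @classmethod
    def from_dataframe(cls, df, pulse: FieldTrace, stack: LayerStack, **kw):
        """Build from a DataFrame with columns ``time_ps`` and
        ``phase_mrad`` (and optionally ``sigma_mrad``)."""
        sigma = None
        if "sigma_mrad" in df:
            sigma = df["sigma_mrad"].to_numpy() * 1e-3
        data = PhaseTrace(df["time_ps"].to_numpy(),
                          df["phase_mrad"].to_numpy() * 1e-3, sigma=sigma)
        return cls(data, pulse, stack, **kw)

    # ---------------------------------------------------------------- core

    def _check_delays(self):
        t = self.field_map.t
        from .constants import C_M_PER_PS
        max_shift = (self.stack.liquid.n_group_probe
                     * self.stack.liquid_thickness / C_M_PER_PS)
        if (self.data.t[0] < t[0] - 1e-9
                or self.data.t[-1] + max_shift > t[-1] + 1e-9):
            raise ValueError("data delays are incompatible with the pulse "
                             "time grid; pad the pulse grid")

    def _tau1(self, tau2: float) -> float:
        if self.tau1_policy == "zero":
            return 0.0
        if self.tau1_policy == "tied":
            return 3.0 * tau2
        return float(self.tau1_policy)

    def _params_from_x(self, x) -> KerrParameters:
        b_e, b_m, tau2 = x
        kw = dict(B_e=b_e * B_SCALE, tau2=tau2, tau1=self._tau1(tau2),
                  T=self.T, lambda_probe=self.lambda_probe)
        if self.kind == "polar":
            kw["B_m2"] = b_m * B_SCALE
        else:
            kw["B_m1"] = abs(b_m) * B_SCALE
        return KerrParameters(**kw)

    def _component_traces(self, params: KerrParameters):
        fm = self.field_map
        dn_e = electronic_birefringence(params, fm.E)
        dn_m = molecular_birefringence(params, fm.E, self._dt, axis=1)
        phi_e = probe_phase(dn_e, self.stack, self.lambda_probe,
                            t=fm.t, z=fm.z, delays=self.data.t)
        phi_m = probe_phase(dn_m, self.stack, self.lambda_probe,
                            t=fm.t, z=fm.z, delays=self.data.t)
        return phi_e, phi_m

    def _model_phi(self, x) -> np.ndarray:
        phi_e, phi_m = self._component_traces(self._params_from_x(x))
        return phi_e.phi + phi_m.phi

    def _residual(self, x) -> np.ndarray:
        return self.weights * (self._model_phi(x) - self.data.phi)

    def _linear_b(self, tau2: float):
        """Solve the linear-in-B subproblem at fixed tau2 (weighted)."""
        unit_e = self._model_phi([1.0, 0.0, tau2])
        unit_m = self._model_phi([0.0, 1.0, tau2])
        A = np.column_stack([unit_e, unit_m]) * self.weights[:, None]
        b, *_ = np.linalg.lstsq(A, self.weights * self.data.phi, rcond=None)
        return b

    def fit(self, init: KerrParameters | None = None, n_starts: int = 3,
            seed: int = 0, xtol: float = 1e-12, ftol: float = 1e-12
            ) -> KerrFitResults:
        """Trust-region least squares with multi-start initialisation.

        Starts are taken on a geometric tau2 grid around a plausible
        relaxation time (or around ``init.tau2`` when given), each with
        the coefficients from the linear subproblem; the best converged
        solution wins.
        """
        rng = np.random.default_rng(seed)
        tau0 = init.tau2 if init is not None else 1.2
        tau_grid = tau0 * np.array([1.0, 0.5, 2.2])[:n_starts]
        tau_grid = tau_grid * (1.0 + 0.05 * rng.standard_normal(tau_grid.size))
        best = None
        for tau2 in tau_grid:
            if init is not None and tau2 is tau_grid[0]:
                x0 = np.array([init.B_e / B_SCALE,
                               (init.B_m2 if self.kind == "polar"
                                else init.B_m1) / B_SCALE, tau2])
            else:
                be, bm = self._linear_b(tau2)
                x0 = np.array([be, bm, tau2])
            try:
                sol = least_squares(self._residual, x0, method="trf",
                                    x_scale=[0.01, 0.01, 1.0],
                                    bounds=([-np.inf, -np.inf, 1e-3],
                                            [np.inf, np.inf, 50.0]),
                                    xtol=xtol, ftol=ftol, gtol=1e-12)
            except Exception:           # keep scanning other starts
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")
        return self._package(best, seed=seed, n_starts=n_starts)

    def _package(self, sol, **config) -> KerrFitResults:
        x = sol.x
        params = self._params_from_x(x)
        phi_e, phi_m = self._component_traces(params)
        total = PhaseTrace(phi_e.t.copy(), phi_e.phi + phi_m.phi)
        resid = self.data.phi - total.phi
        rms = float(np.sqrt(np.mean(resid**2)))
        dof = max(self.data.phi.size - x.size, 1)
        s2 = np.sum((self.weights * resid) ** 2) / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(x.size, np.nan)
        names = ("B_e", "B_m2" if self.kind == "polar" else "B_m1", "tau2")
        return KerrFitResults(
            model=self, params=params, free_names=names, x=x.copy(),
            bse=bse, residual_rms=rms * 1e3, trace_total=total,
            trace_electronic=phi_e, trace_molecular=phi_m,
            converged=bool(sol.success), n_iter=int(sol.nfev),
            message=str(sol.status), config=config)

    # ------------------------------------------------- B_e bound

    def _refit_fixed_be(self, b_e: float, x_init) -> float:
        """RMS (rad) of the best fit with B_e clamped; free (B_m, tau2)."""
        def resid(y):
            return self._residual([b_e, y[0], y[1]])
        sol = least_squares(resid, x_init, method="trf",
                            x_scale=[0.01, 1.0],
                            bounds=([-np.inf, 1e-3], [np.inf, 50.0]),
                            xtol=1e-12, ftol=1e-12)
        return float(np.sqrt(np.mean((self.data.phi
                                      - self._model_phi([b_e, *sol.x])) ** 2)))

    def _bound_electronic(self, results: KerrFitResults, factor: float,
                          scan_max: float) -> float:
        rms_min = results.residual_rms * 1e-3
        target = factor * rms_min
        x_init = results.x[1:].copy()
        sign = np.sign(results.x[0]) or 1.0
        lo, rms_lo = 0.0, self._refit_fixed_be(0.0, x_init)
        if rms_lo >= target:
            return 0.0
        b = max(abs(results.x[0]), 1e-3)
        hi = None
        while b <= scan_max:
            rms = self._refit_fixed_be(sign * b, x_init)
            if rms >= target:
                hi = b
                break
            lo = b
            b *= 2.0
        if hi is None:
            return np.inf
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if self._refit_fixed_be(sign * mid, x_init) >= target:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-4 * hi:
                break
        return hi * B_SCALE


def fit_trace(data: PhaseTrace, pulse: FieldTrace, stack: LayerStack,
              kind: str = "polar", init: KerrParameters | None = None,
              **kwargs) -> KerrFitResults:
    """Convenience wrapper: build a :class:`KerrModel` and fit it."""
    fit_kw = {k: kwargs.pop(k) for k in ("n_starts", "seed") if k in kwargs}
    return KerrModel(data, pulse, stack, kind=kind, **kwargs).fit(
        init=init, **fit_kw)


def bound_electronic_coefficient(results: KerrFitResults,
                                 factor: float = 2.0,
                                 scan_max: float = 1.0) -> float:
    """Residual-doubling upper bound on |B_e| (see
    :meth:`KerrFitResults.bound_electronic`)."""
    return results.bound_electronic(factor=factor, scan_max=scan_max)


# --------------------------------------------------------------------------
# temperature and concentration analyses
# --------------------------------------------------------------------------

@dataclass
class TemperatureDecomposition:
    """Per-delay temperature derivative of the phase trace.

    ``deriv`` is ``-d(phi)/dT`` in rad/K, proportional to the molecular
    contribution alone (the electronic response is temperature
    independent)."""

    t: np.ndarray
    deriv: np.ndarray
    stderr: np.ndarray


def temperature_decomposition(traces: list[PhaseTrace], temperatures,
                              degree: int = 1, T_eval: float | None = None
                              ) -> TemperatureDecomposition:
    """Isolate the molecular trace from a temperature series.

    Fits, per delay point, a polynomial of ``phi`` against ``T`` and
    returns the negated derivative (evaluated at ``T_eval``, default the
    series mean) with its standard error.  Requires at least three
    temperatures spanning at least 20 K on a common delay grid.
    """
    T = np.asarray(temperatures, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 temperatures")
    if T.max() - T.min() < 20.0:
        raise ValueError("temperature span must be at least 20 K")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or np.max(np.abs(tr.t - t0)) > 1e-9:
            raise ValueError("traces must share a common delay grid")
    Y = np.stack([tr.phi for tr in traces])          # (n_T, n_delay)
    Tc = T - T.mean()
    V = np.vander(Tc, degree + 1)                    # columns: Tc^deg .. 1
    coef, *_ = np.linalg.lstsq(V, Y, rcond=None)
    fitted = V @ coef
    dof = max(T.size - (degree + 1), 1)
    s2 = np.sum((Y - fitted) ** 2, axis=0) / dof
    # derivative of the fitted polynomial at T_eval
    tc = 0.0 if T_eval is None else float(T_eval) - T.mean()
    powers = np.arange(degree, -1, -1)
    dvec = np.where(powers >= 1, powers * tc ** np.clip(powers - 1, 0, None),
                    0.0)
    slope = dvec @ coef
    cov = np.linalg.inv(V.T @ V)
    var_factor = float(dvec @ cov @ dvec)
    stderr = np.sqrt(s2 * var_factor)
    return TemperatureDecomposition(t0.copy(), -slope, stderr)


@dataclass
class ConcentrationTrend:
    slope: float          # m/V^2 per mol/L
    intercept: float      # m/V^2
    r_squared: float
    residuals: np.ndarray


def concentration_trend(molarities, values) -> ConcentrationTrend:
    """Ordinary least squares of a coefficient against molarity.

    ``values`` may be fitted coefficients (m/V^2) or
    :class:`KerrFitResults`, from which the free molecular coefficient is
    taken.
    """
    c = np.asarray(molarities, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 concentrations")
    vals = []
    for v in values:
        if isinstance(v, KerrFitResults):
            p = v.params
            vals.append(p.B_m2 if v.model.kind == "polar" else p.B_m1)
        else:
            vals.append(float(v))
    y = np.asarray(vals)
    A = np.column_stack([c, np.ones_like(c)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0)
    return ConcentrationTrend(float(coef[0]), float(coef[1]), float(r2), resid)
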