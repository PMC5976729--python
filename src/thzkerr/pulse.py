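"""Synthetic single-cycle THz waveforms and spectral utilities.

The generator produces the first derivative of a Gaussian: the simplest
carrier-envelope-phase-stable, strictly zero-area single-cycle waveform.
A free-space THz pulse must have zero area (its spectrum vanishes at DC),
and this property is what makes the orientation term of the Kerr response
sensitive to the sign of the molecular coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
import numpy as np
from scipy.ndimage import gaussian_filter1d


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if t.size < 2:
        raise ValueError("time grid needs at least two samples")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * abs(dt[0]):
        raise ValueError("time grid must be uniform (within 1e-9 relative)")
    return float(dt[0])


@dataclass
class FieldTrace:
    """Uniformly sampled electric-field waveform.

    ``t`` in ps, ``E`` in V/m.  ``meta`` carries free-form provenance
    (peak field, description, seed).
    """

    t: np.ndarray
    E: np.ndarray
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.t.shape != self.E.shape or self.t.ndim != 1:
            raise ValueError("t and E must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.E))):
            raise ValueError("non-finite values in field trace")
        self.dt = _check_uniform(self.t)

    @property
    def area(self) -> float:
        """Trapezoid integral of E over t (V/m * ps)."""
        return float(np.trapezoid(self.E, self.t))

    @property
    def energy(self) -> float:
        """Trapezoid integral of E^2 (proportional to fluence)."""
        return float(np.trapezoid(self.E**2, self.t))

    def with_field(self, E: np.ndarray, **meta) -> "FieldTrace":
        return FieldTrace(self.t.copy(), np.asarray(E, dtype=float),
                          {**self.meta, **meta})


@dataclass
class Spectrum:
    """One-sided complex amplitude spectrum of a real field trace.

    ``f`` in THz; ``A`` is ``rfft(E) * dt`` so amplitudes approximate the
    continuous Fourier integral.  ``n`` and ``t0`` are kept for an exact
    inverse transform.
    """

    f: np.ndarray
    A: np.ndarray
    n: int
    t0: float

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0])


def to_spectrum(trace: FieldTrace) -> Spectrum:
    A = np.fft.rfft(trace.E) * trace.dt
    f = np.fft.rfftfreq(trace.t.size, trace.dt)
    return Spectrum(f, A, trace.t.size, float(trace.t[0]))


def from_spectrum(spec: Spectrum) -> FieldTrace:
    dt = 1.0 / (spec.n * spec.df)
    E = np.fft.irfft(spec.A / dt, spec.n)
    t = spec.t0 + dt * np.arange(spec.n)
    return FieldTrace(t, E)


def synth_single_cycle(peak_field: float, center_freq: float,
                       t: np.ndarray | None = None, *,
                       t_start: float = -10.0, t_stop: float = 25.0,
                       dt: float = 0.02, t0: float = 0.0) -> FieldTrace:
    """Generate a single-cycle, zero-area THz pulse.

    The waveform is ``E(t) = -A (t-t0)/sigma * exp(-(t-t0)^2 / 2 sigma^2)``
    with ``sigma = 1/(2 pi f_c)``, whose amplitude spectrum peaks exactly at
    ``f_c``.  ``A`` is normalised so the sampled ``max |E|`` equals
    ``peak_field``.

    Parameters
    ----------
    peak_field : float
        Peak electric field, V/m (e.g. 5.1e7 for 510 kV/cm).
    center_freq : float
        Spectral-amplitude maximum, THz.
    t : array, optional
        Explicit uniform time grid (ps); otherwise built from
        ``t_start, t_stop, dt``.
    """
    if peak_field <= 0:
        raise ValueError("peak_field must be positive")
    if center_freq <= 0:
        raise ValueError("center_freq must be positive")
    if t is None:
        t = np.arange(t_start, t_stop + 0.5 * dt, dt)
    t = np.asarray(t, dtype=float)
    _check_uniform(t)
    span = t[-1] - t[0]
    if span < 6.0 / center_freq:
        raise ValueError(
            f"time grid spans {span:.2f} ps but at least "
            f"{6.0 / center_freq:.2f} ps (6 cycles of {center_freq} THz) "
            "are required"
        )
    sigma = 1.0 / (2.0 * np.pi * center_freq)
    x = (t - t0) / sigma
    E = -x * np.exp(-0.5 * x**2)
    E *= peak_field / np.max(np.abs(E))
    return FieldTrace(t, E, {"peak_field": peak_field,
                             "center_freq": center_freq,
                             "description": "Gaussian-derivative single cycle"})


def center_frequency(trace: FieldTrace) -> float:
    """Amplitude-spectrum argmax in THz, parabolically interpolated.

    The centre frequency of a pulse is defined here as the location of the
    maximum of the single-sided amplitude spectrum (the centroid is an
    alternative definition, not used).
    """
    if np.max(np.abs(trace.E)) == 0:
        raise ValueError("cannot determine center frequency of an all-zero trace")
    spec = to_spectrum(trace)
    mag = np.abs(spec.A)
    k = int(np.argmax(mag[1:]) + 1)  # exclude DC
    if 1 <= k < mag.size - 1:
        y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * spec.df)


def smooth_array(y: np.ndarray, sigma_ps: float, dt: float) -> np.ndarray:
    """Gaussian convolution with reflected edges; area preserving."""
    if sigma_ps < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_ps == 0:
        return np.asarray(y, dtype=float).copy()
    return gaussian_filter1d(np.asarray(y, dtype=float), sigma_ps / dt,
                             mode="reflect")


def smooth_trace(trace, sigma_ps: float):
    """Gaussian-smooth a sampled trace (FieldTrace or PhaseTrace alike).

    Emulates probing with a longer pulse: convolution with a normalised
    Gaussian of width ``sigma_ps`` (the slow-probe comparison uses 1.4 ps).
    """
    if isinstance(trace, FieldTrace):
        return trace.with_field(smooth_array(trace.E, sigma_ps, trace.dt),
                                smoothed_sigma_ps=sigma_ps)
    # duck-typed phase trace: has .t and .phi
    from .propagation import PhaseTrace
    if isinstance(trace, PhaseTrace):
        dt = float(trace.t[1] - trace.t[0])
        return PhaseTrace(trace.t.copy(),
                          smooth_array(trace.phi, sigma_ps, dt),
                          sigma=None if trace.sigma is None else trace.sigma.copy(),
                          meta={**trace.meta, "smoothed_sigma_ps": sigma_ps})
    raise TypeError(f"cannot smooth object of type {type(trace).__name__}")
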