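"""Synthetic experiment generator: complete pump-probe datasets with the
statistical structure the analysis assumes.

The generator runs the full forward model (pulse -> cuvette propagation ->
Kerr response -> probe phase) and adds the two noise channels of the
measurement: per-point pulse-to-pulse amplitude jitter (multiplicative on
the field, hence quadratic on the phase trace) and additive white
detection noise on the phase.  Fixture configurations preload the
tabulated fitted coefficients of the studied liquids as ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace
import numpy as np

from .constants import T_REF
from .materials import get_material
from .propagation import LayerStack, PhaseTrace, cuvette_stack
from .pulse import FieldTrace, synth_single_cycle
from .response import KerrParameters, forward_phase_model

#: default noise calibration: 1% field jitter, 0.01 mrad additive
DEFAULT_JITTER = 0.01
DEFAULT_NOISE_MRAD = 0.01


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to synthesise one experiment."""

    liquid: str
    kerr: KerrParameters
    window: str = "silica"
    window_thickness: float = 1.2e-3
    liquid_thickness: float = 0.2e-3
    peak_field: float = 5.1e7          # 510 kV/cm in V/m
    center_freq: float = 0.25          # THz
    jitter: float = DEFAULT_JITTER
    noise_mrad: float = DEFAULT_NOISE_MRAD
    temperatures: tuple[float, ...] = (T_REF,)
    molarity: float | None = None
    seed: int = 0
    t_start: float = -10.0
    t_stop: float = 25.0
    dt: float = 0.02
    n_z: int = 64
    label: str = ""

    def __post_init__(self) -> None:
        if self.jitter < 0 or self.noise_mrad < 0:
            raise ValueError("noise fractions must be >= 0")
        if self.window_thickness < 0 or self.liquid_thickness <= 0:
            raise ValueError("geometry must be positive")
        get_material(self.liquid)  # raises with the built-in list

    def stack(self) -> LayerStack:
        return cuvette_stack(get_material(self.liquid),
                             self.liquid_thickness,
                             get_material(self.window),
                             self.window_thickness)

    def pulse(self) -> FieldTrace:
        return synth_single_cycle(self.peak_field, self.center_freq,
                                  t_start=self.t_start, t_stop=self.t_stop,
                                  dt=self.dt)

    def replace(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


@dataclass
class ConditionRecord:
    """One condition (temperature) of a synthetic dataset."""

    temperature: float
    clean: PhaseTrace
    noisy: PhaseTrace


@dataclass
class SyntheticDataset:
    config: ExperimentConfig
    pulse: FieldTrace
    stack: LayerStack
    truth: KerrParameters
    records: list[ConditionRecord] = dfield(default_factory=list)

    @property
    def noisy(self) -> PhaseTrace:
        return self.records[0].noisy

    @property
    def clean(self) -> PhaseTrace:
        return self.records[0].clean


def generate_experiment(config: ExperimentConfig) -> SyntheticDataset:
    """Synthesise clean and noisy phase traces for every temperature.

    Fully reproducible from ``config.seed``.  The jitter enters as a
    per-delay multiplicative field fluctuation ``(1 + g xi)^2`` on the
    phase (each delay point is recorded on a different pump shot), the
    detection noise as additive white Gaussian phase noise.
    """
    rng = np.random.default_rng(config.seed)
    pulse = config.pulse()
    stack = config.stack()
    ds = SyntheticDataset(config, pulse, stack, config.kerr)
    field_map = None
    for T in config.temperatures:
        params = config.kerr.replace(T=T)
        fwd = forward_phase_model(params, pulse, stack, n_z=config.n_z,
                                  field_map=field_map)
        field_map = fwd.field_map
        clean = fwd.total
        amp = (1.0 + config.jitter * rng.standard_normal(clean.phi.size)) ** 2
        noise = 1e-3 * config.noise_mrad * rng.standard_normal(clean.phi.size)
        noisy = PhaseTrace(clean.t.copy(), clean.phi * amp + noise,
                           sigma=np.full(clean.phi.size,
                                         1e-3 * config.noise_mrad),
                           meta={"temperature_K": T, "seed": config.seed})
        ds.records.append(ConditionRecord(T, clean, noisy))
    return ds


# --------------------------------------------------------------------------
# fixtures preloaded with the tabulated fitted coefficients (ground truth)
# --------------------------------------------------------------------------

_B = 1e-14  # coefficient scale, m/V^2

#: polar liquids use a small electronic coefficient inside the reported
#: |B_e| < 0.003e-14 m/V^2 bound so the electronic channel is exercised.
_BE_POLAR = 0.002 * _B


def water_fixture(seed: int = 0, **kw) -> ExperimentConfig:
    """Liquid water: B_m2 = -0.025e-14 m/V^2, tau2 = 1.1 ps."""
    kerr = KerrParameters(B_e=_BE_POLAR, B_m2=-0.025 * _B, tau1=0.0,
                          tau2=1.1)
    return ExperimentConfig("water", kerr, seed=seed, label="water", **kw)


def d2o_fixture(seed: int = 0, **kw) -> ExperimentConfig:
    """Heavy water: B_m2 = -0.021e-14 m/V^2, tau2 = 1.36 ps (24% slower)."""
    kerr = KerrParameters(B_e=_BE_POLAR, B_m2=-0.021 * _B, tau1=0.0,
                          tau2=1.36)
    return ExperimentConfig("d2o", kerr, seed=seed, label="d2o", **kw)


#: NaI series ground truth: molarity -> (material, B_m2 / 1e-14, tau2)
_NAI_ROWS = {
    1.0: ("nai-1m", -0.027, 1.1),
    3.0: ("nai-3m", -0.043, 1.1),
    5.0: ("nai-5m", -0.071, 1.0),
    9.5: ("nai-9.5m", -0.102, 1.0),
}


def nai_series_fixture(seed: int = 0, **kw) -> list[ExperimentConfig]:
    """Sodium-iodide concentration series at 1, 3, 5 and 9.5 M."""
    out = []
    for i, (mol, (name, b, tau2)) in enumerate(sorted(_NAI_ROWS.items())):
        kerr = KerrParameters(B_e=_BE_POLAR, B_m2=b * _B, tau1=0.0, tau2=tau2)
        out.append(ExperimentConfig(name, kerr, molarity=mol,
                                    seed=seed + 101 * i,
                                    label=f"nai-{mol}m", **kw))
    return out


_ALCOHOL_ROWS = {
    "methanol": (0.016, -0.018, 1.46),
    "ethanol": (0.0093, -0.0067, 0.96),
    "2-propanol": (0.0097, -0.0033, 1.52),
}


def alcohol_fixtures(seed: int = 0, **kw) -> dict[str, ExperimentConfig]:
    """Methanol, ethanol and 2-propanol with their tabulated coefficients."""
    out = {}
    for i, (name, (be, bm2, tau2)) in enumerate(_ALCOHOL_ROWS.items()):
        kerr = KerrParameters(B_e=be * _B, B_m2=bm2 * _B, tau1=0.0, tau2=tau2)
        out[name] = ExperimentConfig(name, kerr, seed=seed + 211 * i,
                                     label=name, **kw)
    return out


def nonpolar_fixtures(seed: int = 0, **kw) -> dict[str, ExperimentConfig]:
    """CS2 (2 mm cuvette) and benzene: positive alignment coefficients.

    The CS2 row values are marked low-confidence in the source table
    (parsed: B_e = 0.28e-14, B_m1 = 0.22e-14, tau2 = 1.84 ps).
    """
    cs2 = ExperimentConfig(
        "cs2",
        KerrParameters(B_e=0.28 * _B, B_m1=0.22 * _B, tau1=0.0, tau2=1.84),
        liquid_thickness=2.0e-3, seed=seed, label="cs2", **kw)
    benzene = ExperimentConfig(
        "benzene",
        KerrParameters(B_e=0.035 * _B, B_m1=0.029 * _B, tau1=0.0, tau2=1.55),
        seed=seed + 1, label="benzene", **kw)
    return {"cs2": cs2, "benzene": benzene}


def water_temperature_fixture(seed: int = 0,
                              temperatures=(296.0, 305.0, 314.0, 323.0,
                                            332.0, 341.0),
                              **kw) -> ExperimentConfig:
    """Water fixture with the 23-68 C temperature series."""
    return water_fixture(seed=seed, temperatures=tuple(temperatures), **kw)


FIXTURES = {
    "water": water_fixture,
    "d2o": d2o_fixture,
}
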