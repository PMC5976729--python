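"""Shared delimited-text file formats with provenance headers.

All traces are tab-separated text: '#'-prefixed provenance comment lines,
then a mandatory column-header line (first column always ``time_ps`` or
``freq_THz``), then the data.  Units live in the header names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .materials import DielectricTable
from .propagation import PhaseTrace
from .pulse import FieldTrace


def _provenance(extra: dict | None = None) -> list[str]:
    lines = [f"# thzkerr {__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k} = {v}")
    return lines


def _write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n".join(_provenance(meta)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc


def write_field_trace(path, trace: FieldTrace, meta: dict | None = None) -> None:
    df = pd.DataFrame({"time_ps": trace.t, "field_V_per_m": trace.E})
    _write_table(path, df, {**trace.meta, **(meta or {})})


def read_field_trace(path) -> FieldTrace:
    df = _read_table(path)
    _require(df, path, "time_ps", "field_V_per_m")
    return FieldTrace(df["time_ps"].to_numpy(), df["field_V_per_m"].to_numpy())


def write_phase_trace(path, trace: PhaseTrace, meta: dict | None = None) -> None:
    cols = {"time_ps": trace.t, "phase_mrad": trace.phi_mrad}
    if trace.sigma is not None:
        cols["sigma_mrad"] = trace.sigma * 1e3
    m = {"delay_origin": "pump peak at liquid entrance",
         **trace.meta, **(meta or {})}
    _write_table(path, pd.DataFrame(cols), m)


def read_phase_trace(path) -> PhaseTrace:
    df = _read_table(path)
    _require(df, path, "time_ps", "phase_mrad")
    sigma = (df["sigma_mrad"].to_numpy() * 1e-3
             if "sigma_mrad" in df else None)
    return PhaseTrace(df["time_ps"].to_numpy(),
                      df["phase_mrad"].to_numpy() * 1e-3, sigma=sigma)


def write_dielectric_table(path, table: DielectricTable,
                           meta: dict | None = None) -> None:
    df = pd.DataFrame({"freq_THz": table.freqs,
                       "eps_real": table.eps.real,
                       "eps_imag": table.eps.imag})
    _write_table(path, df, meta)


def read_dielectric_table(path) -> DielectricTable:
    df = _read_table(path)
    _require(df, path, "freq_THz", "eps_real", "eps_imag")
    return DielectricTable(df["freq_THz"].to_numpy(),
                           df["eps_real"].to_numpy()
                           + 1j * df["eps_imag"].to_numpy())


def _require(df: pd.DataFrame, path, *cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing} "
                         f"(header line required)")


# ----------------------------------------------------------------- configs

def config_to_json(config) -> str:
    d = asdict(config) if is_dataclass(config) else dict(config)
    return json.dumps(d, indent=2, default=str)


def config_hash(config) -> str:
    return hashlib.sha256(config_to_json(config).encode()).hexdigest()[:12]


def load_experiment_config(path):
    from .response import KerrParameters
    from .synthetic import ExperimentConfig
    with open(path) as fh:
        d = json.load(fh)
    kerr = KerrParameters(**d.pop("kerr"))
    if "temperatures" in d:
        d["temperatures"] = tuple(d["temperatures"])
    return ExperimentConfig(kerr=kerr, **d)


def write_dataset(directory, dataset) -> Path:
    """Write a SyntheticDataset as a directory of traces plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    meta = {"seed": cfg.seed, "config_hash": config_hash(cfg)}
    write_field_trace(directory / "pulse.txt", dataset.pulse, meta)
    entries = []
    for rec in dataset.records:
        tag = f"T{rec.temperature:.0f}K"
        for kind, trace in (("clean", rec.clean), ("noisy", rec.noisy)):
            name = f"trace_{tag}_{kind}.txt"
            write_phase_trace(directory / name, trace,
                              {**meta, "temperature_K": rec.temperature})
            entries.append({"file": name, "temperature_K": rec.temperature,
                            "kind": kind})
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": meta["config_hash"],
        "config": json.loads(config_to_json(cfg)),
        "truth": json.loads(config_to_json(dataset.truth)),
        "traces": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory
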