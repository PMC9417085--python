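"""Readers, writers and run configuration.

File formats are deliberately plain: ASCII SANS columns (see
:func:`surfprot.sas.read_sans`), two-column CSV spectra, three-column
CSV ITC schedules, JSON reports and YAML run configuration. Every
report embeds the fully resolved configuration and seed so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchtop import CDSpectrum, EmissionSpectrum, Enthalpogram
from .sas import ScatteringCurve, read_sans, write_sans  # re-exported

__all__ = [
    "RunConfig",
    "read_sans",
    "write_sans",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_cd_csv",
    "read_itc_csv",
    "write_itc_csv",
    "write_report",
]


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    ``inputs`` maps contrast labels to curve file paths; ``constants``
    carries overrides of the documented defaults (water SLDs, v_SDS,
    exchange fraction, ...); ``options`` holds subcommand-specific
    settings such as the free-parameter mask.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    model: str = "core_shell_ellipsoid"
    free: list[str] = field(
        default_factory=lambda: [
            "radius",
            "axial_ratio",
            "shell_thickness",
            "coverage",
            "charge",
        ]
    )
    constants: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        missing = [p for p in cfg.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input files not found: {missing}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "model": self.model,
            "free": list(self.free),
            "constants": dict(self.constants),
            "options": dict(self.options),
            "seed": self.seed,
            "outdir": self.outdir,
        }


def read_spectrum_csv(path, kind: str = "emission"):
    """Read a two-column (wavelength, value) CSV spectrum.

    ``kind``: 'emission' -> EmissionSpectrum, 'cd' -> CDSpectrum
    (values taken as mean residue ellipticity).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    meta = {"source": str(path)}
    if kind == "emission":
        return EmissionSpectrum(wl, val, metadata=meta)
    if kind == "cd":
        return CDSpectrum(wl, val, metadata=meta)
    raise ValueError(f"unknown spectrum kind {kind!r}")


def write_spectrum_csv(path, spectrum) -> None:
    if isinstance(spectrum, EmissionSpectrum):
        cols = {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
    elif isinstance(spectrum, CDSpectrum):
        cols = {"wavelength_nm": spectrum.wavelength, "theta_mr": spectrum.theta_mr}
    else:
        raise TypeError(f"cannot write {type(spectrum).__name__} as a spectrum")
    pd.DataFrame(cols).to_csv(path, index=False)


def read_cd_csv(path) -> CDSpectrum:
    return read_spectrum_csv(path, kind="cd")


def read_itc_csv(path, protein_um: float | None = None) -> Enthalpogram:
    """Read an integrated ITC titration from CSV.

    Expected columns: ``sds_mm`` (cumulative, dilution-corrected SDS in
    the cell) and ``heat_kcal_per_mol``; optional ``protein_um`` column
    or argument for the cell protein concentration.
    """
    df = pd.read_csv(path)
    required = {"sds_mm", "heat_kcal_per_mol"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if protein_um is None:
        if "protein_um" in df.columns:
            protein_um = float(df["protein_um"].iloc[0])
        else:
            raise ValueError(f"{path}: protein concentration not given")
    return Enthalpogram(
        sds_mm=df["sds_mm"].to_numpy(dtype=float),
        heat=df["heat_kcal_per_mol"].to_numpy(dtype=float),
        protein_um=float(protein_um),
        metadata={"source": str(path)},
    )


def write_itc_csv(path, enthalpogram: Enthalpogram) -> None:
    pd.DataFrame(
        {
            "sds_mm": enthalpogram.sds_mm,
            "heat_kcal_per_mol": enthalpogram.heat,
            "protein_um": enthalpogram.protein_um,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(path, payload: dict, config: RunConfig | None = None) -> None:
    """Write a JSON report embedding the resolved configuration."""
    body = _jsonable(dict(payload))
    if config is not None:
        body["config"] = _jsonable(config.to_dict())
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1)
        fh.write("\n")
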