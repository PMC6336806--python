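"""File formats: delimited signal/spectrum text files, manifests, stamped CSVs.

All tabular outputs are plain CSV with a single ``# config_hash=`` comment
line before the header so a result file can always be traced back to the
exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .reconstruct import IrregularSeries, UniformSeries
from .spectral import EmissionSpectrum, ExtinctionTable

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_signal",
    "read_signal",
    "write_spectra",
    "read_spectra",
    "read_extinction_table",
    "write_truth",
]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a configuration dictionary."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Path | str, cfg_hash: str = "", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def read_csv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_signal(series: UniformSeries, path: Path | str) -> None:
    """Two-column t_seconds,value text file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        path,
        np.column_stack([series.times, series.values]),
        delimiter=",",
        header="t_seconds,value",
        comments="",
        fmt="%.10g",
    )


def read_signal(
    path: Path | str, label: str = "", windows: dict | None = None
) -> UniformSeries:
    """Read a uniformly sampled t_seconds,value file; infers the rate."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: sampling is not uniform")
    return UniformSeries(
        fs_hz=1.0 / dt[0], t0_seconds=float(t[0]), values=v, label=label,
        windows=windows or {},
    )


def read_irregular(path: Path | str, label: str = "") -> IrregularSeries:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return IrregularSeries(t_seconds=arr[:, 0], values=arr[:, 1], label=label)


def write_spectra(spectra: list[EmissionSpectrum], directory: Path | str) -> Path:
    """One wavelength_nm,intensity file per timepoint plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, spec in enumerate(spectra):
        name = f"spectrum_{k:03d}.csv"
        np.savetxt(
            directory / name,
            np.column_stack([spec.wavelengths_nm, spec.intensities]),
            delimiter=",",
            header="wavelength_nm,intensity",
            comments="",
            fmt="%.10g",
        )
        rows.append({"file": name, "t_minutes": spec.t_minutes})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_spectra(manifest: Path | str) -> list[EmissionSpectrum]:
    """Read spectra listed in a manifest CSV (columns file,t_minutes)."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    spectra = []
    for _, row in table.iterrows():
        arr = np.loadtxt(manifest.parent / row["file"], delimiter=",", skiprows=1)
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=arr[:, 0], intensities=arr[:, 1],
                t_minutes=float(row["t_minutes"]),
            )
        )
    return spectra


def read_extinction_table(path: Path | str) -> ExtinctionTable:
    """CSV with columns wavelength_nm,eps_oxy,eps_deoxy."""
    df = pd.read_csv(path, comment="#")
    return ExtinctionTable(
        wavelengths_nm=df["wavelength_nm"].to_numpy(float),
        eps_oxy=df["eps_oxy"].to_numpy(float),
        eps_deoxy=df["eps_deoxy"].to_numpy(float),
    )


def write_truth(truth: dict, path: Path | str) -> None:
    """Ground-truth record as JSON (numpy types coerced)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def coerce(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=coerce)
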