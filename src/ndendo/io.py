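"""Readers and writers for the delimited-text formats the pipeline uses.

PMF profiles travel as two-column text in the xvg dialect (comment lines
prefixed ``#`` or ``@``) or CSV; umbrella windows as one single-column
z file per window plus a CSV manifest; assays and calibrations as
long-format CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pmf import PMFProfile, UmbrellaWindowSet
from .uptake import ASSAY_COLUMNS, CalibrationSeries, validate_assay


def write_xvg(path, profile: PMFProfile, title: str = "Potential of mean force") -> None:
    """Write a PMF as two-column xvg-dialect text (z in nm, F in kcal/mol)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f'@    title "{title}"\n')
        fh.write('@    xaxis  label "z (nm)"\n')
        fh.write('@    yaxis  label "F (kcal/mol)"\n')
        fh.write(f"# reference: {profile.reference_convention}\n")
        for z, f in zip(profile.z_grid, profile.free_energy):
            if np.isfinite(f):
                fh.write(f"{z:.6f} {f:.6f}\n")


def read_xvg(path) -> PMFProfile:
    """Read a two-column xvg-dialect PMF file, skipping #/@ comment lines."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows)
    return PMFProfile(z_grid=arr[:, 0], free_energy=arr[:, 1])


def write_pmf_csv(path, profile: PMFProfile) -> None:
    df = pd.DataFrame({"z_nm": profile.z_grid, "free_energy_kcal_mol": profile.free_energy})
    if profile.error is not None:
        df["error_kcal_mol"] = profile.error
    df.to_csv(path, index=False)


def write_windows(directory, windows: UmbrellaWindowSet, prefix: str = "window") -> Path:
    """Write per-window z samples and a manifest CSV; returns manifest path."""
    if windows.samples is None:
        raise ValueError("can only write raw-sample window sets")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (z0, samp) in enumerate(zip(windows.centers, windows.samples)):
        fname = f"{prefix}_{i:03d}.dat"
        np.savetxt(directory / fname, samp, fmt="%.8f", header="z_nm")
        records.append({
            "window": i, "center_nm": z0,
            "force_constant_kcal_mol_nm2": windows.force_constant,
            "temperature_K": windows.temperature, "file": fname,
        })
    manifest = directory / f"{prefix}_manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_windows(manifest_path) -> UmbrellaWindowSet:
    """Read an umbrella window set from a manifest CSV written by write_windows."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"center_nm", "force_constant_kcal_mol_nm2", "temperature_K", "file"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(man.columns))}")
    k = man["force_constant_kcal_mol_nm2"].unique()
    temp = man["temperature_K"].unique()
    if len(k) != 1 or len(temp) != 1:
        raise ValueError("all windows must share force constant and temperature")
    samples = [
        np.loadtxt(manifest_path.parent / f, ndmin=1) for f in man["file"]
    ]
    return UmbrellaWindowSet(
        centers=man["center_nm"].to_numpy(), force_constant=float(k[0]),
        temperature=float(temp[0]), samples=samples,
    )


def read_assay(path) -> pd.DataFrame:
    """Read a long-format assay CSV (nd_type, condition, time_hr, replicate, intensity)."""
    df = pd.read_csv(path)
    df["condition"] = df["condition"].astype(str)
    return validate_assay(df[ASSAY_COLUMNS])


def write_assay(path, assay: pd.DataFrame) -> None:
    validate_assay(assay)
    assay.to_csv(path, index=False)


def read_calibration(path) -> dict[str, CalibrationSeries]:
    """Read a calibration CSV (nd_type, concentration, intensity) into series."""
    df = pd.read_csv(path)
    out = {}
    for nd_type, grp in df.groupby("nd_type"):
        out[str(nd_type)] = CalibrationSeries(
            nd_type=str(nd_type),
            concentrations=grp["concentration"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
        )
    return out


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
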