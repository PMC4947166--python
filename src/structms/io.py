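"""File dialects: delimited peak lists, ATD manifests, CCSD CSVs and
family-set JSON.

All formats are plain text.  Peak lists and ATDs are two-column delimited
files (whitespace or comma), `#` comments allowed, header row optional.
Metadata travels in `key = value` sidecars or manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conformers import GaussianFamily
from .mobility import ATDSet, CCSD, DriftRun
from .spectra import Spectrum


def _read_two_columns(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    # drop a header row if the first row is not numeric
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
    arr = df.astype(float).to_numpy()
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return arr[:, 0], arr[:, 1]


def read_keyvalue(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected 'key = value', got {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_peaklist(path, sidecar=None, cone_voltage: float | None = None, label: str = "") -> Spectrum:
    """Two-column (m/z, intensity) delimited text -> Spectrum.

    A `key = value` sidecar may supply cone_voltage and label; explicit
    arguments win.
    """
    mz, inten = _read_two_columns(path)
    order = np.argsort(mz)
    meta = read_keyvalue(sidecar) if sidecar else {}
    if cone_voltage is None and "cone_voltage" in meta:
        cone_voltage = float(meta["cone_voltage"])
    label = label or meta.get("label", "")
    return Spectrum(mz=mz[order], intensity=inten[order], cone_voltage=cone_voltage, label=label)


def write_peaklist(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# mz_Th\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def read_atd_manifest(path) -> ATDSet:
    """Manifest -> ATDSet.

    Format: `key = value` lines for the globals drift_length (cm), ion_mass
    (Da), buffer_gas_mass (Da) and charge, plus one
    `run: <file> <V> <P_torr> <T_K>` line per drift voltage.  Run paths are
    resolved relative to the manifest.
    """
    base = Path(path).parent
    globals_: dict[str, str] = {}
    runs: list[DriftRun] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("run:"):
            fields = line[4:].split()
            if len(fields) != 4:
                raise ValueError(f"bad run line: {line!r}")
            fname, v, p, t = fields
            ta, inten = _read_two_columns(base / fname)
            runs.append(DriftRun(t=ta, intensity=inten, voltage=float(v),
                                 pressure=float(p), temperature=float(t)))
        elif "=" in line:
            k, val = line.split("=", 1)
            globals_[k.strip()] = val.strip()
        else:
            raise ValueError(f"unparseable manifest line: {line!r}")
    return ATDSet(
        runs=runs,
        drift_length=float(globals_.get("drift_length", 5.1)),
        ion_mass=float(globals_["ion_mass"]),
        buffer_gas_mass=float(globals_.get("buffer_gas_mass", 4.002602)),
        charge=int(globals_["charge"]),
    )


def write_atdset(atdset: ATDSet, directory, stem: str = "run") -> Path:
    """Write per-run ATD files plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        f"drift_length = {atdset.drift_length}",
        f"ion_mass = {atdset.ion_mass}",
        f"buffer_gas_mass = {atdset.buffer_gas_mass}",
        f"charge = {atdset.charge}",
    ]
    for i, run in enumerate(atdset.runs):
        fname = f"{stem}_{i:02d}.tsv"
        with open(directory / fname, "w") as fh:
            fh.write("# t_ms\tintensity\n")
            for t, y in zip(run.t, run.intensity):
                fh.write(f"{t:.6f}\t{y:.6f}\n")
        lines.append(f"run: {fname} {run.voltage} {run.pressure} {run.temperature}")
    manifest = directory / f"{stem}_manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def write_ccsd_csv(ccsd: CCSD, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# charge = {ccsd.charge}\n# label = {ccsd.label}\n")
        fh.write("ccs_A2,intensity\n")
        for g, y in zip(ccsd.grid, ccsd.intensity):
            fh.write(f"{g:.4f},{y:.6f}\n")


def read_ccsd_csv(path) -> CCSD:
    charge, label = 1, ""
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line.lstrip("#").split("=", 1)
            if k.strip() == "charge":
                charge = int(v)
            elif k.strip() == "label":
                label = v.strip()
    grid, inten = _read_two_columns(path)
    return CCSD(grid=grid, intensity=inten, charge=charge, label=label)


def families_to_json(families: list[GaussianFamily], path) -> None:
    data = [{"centre": f.centre, "sigma": f.sigma, "label": f.label} for f in families]
    Path(path).write_text(json.dumps(data, indent=1))


def families_from_json(path) -> list[GaussianFamily]:
    data = json.loads(Path(path).read_text())
    return [GaussianFamily(centre=d["centre"], sigma=d["sigma"], label=d.get("label", "")) for d in data]
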