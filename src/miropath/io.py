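"""Readers and writers for the pipeline's on-disk formats.

Scan cubes go to a single HDF5 file (one group per scan, datasets
``transients`` and ``wavenumbers`` plus scalar attributes), micrographs to
16-bit grayscale TIFF with the linear scaling recorded in the description
tag, and spectral datasets to CSV with one row per spectrum and one column
per wavenumber.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .containers import KIND_NOAS2, KIND_RAW_PTP, Micrograph, ScanCube, SpectralDataset, Stage
from .grid import WavenumberGrid

_SCAN_GROUP = "scan"


class FormatError(ValueError):
    """A container does not conform to the expected layout."""


def write_scan(cube: ScanCube, path) -> Path:
    """Write a :class:`ScanCube` to an HDF5 container; round-trips exactly."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group(_SCAN_GROUP)
        g.create_dataset("transients", data=cube.transients)
        g.create_dataset("wavenumbers", data=cube.grid.values)
        g.create_dataset(
            "band_labels", data=np.char.encode(cube.grid.band_labels.astype("U1"), "ascii")
        )
        g.attrs["step_size_um"] = float(cube.step_size_um)
        g.attrs["n_averages"] = int(cube.n_averages)
        g.attrs["subject_id"] = cube.subject_id
        g.attrs["acquired"] = cube.acquired
    return path


def read_scan(path) -> ScanCube:
    """Read a scan container written by :func:`write_scan`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if _SCAN_GROUP not in f:
            raise FormatError(f"{path}: missing group '{_SCAN_GROUP}'")
        g = f[_SCAN_GROUP]
        for name in ("transients", "wavenumbers"):
            if name not in g:
                raise FormatError(f"{path}: missing dataset '{_SCAN_GROUP}/{name}'")
        values = np.asarray(g["wavenumbers"])
        labels = (
            np.char.decode(np.asarray(g["band_labels"]), "ascii")
            if "band_labels" in g
            else None
        )
        grid = WavenumberGrid(values, labels)
        return ScanCube(
            transients=np.asarray(g["transients"]),
            grid=grid,
            step_size_um=float(g.attrs.get("step_size_um", 5.0)),
            n_averages=int(g.attrs.get("n_averages", 50)),
            subject_id=str(g.attrs.get("subject_id", "")),
            acquired=str(g.attrs.get("acquired", "")),
        )


# -- micrograph TIFF ------------------------------------------------------

def export_micrograph_tiff(m: Micrograph, path) -> Path:
    """Write a micrograph as 16-bit grayscale TIFF.

    Values are scaled linearly over the map's nominal range (0..1 for NOAS^2,
    0..max(mV) for raw peak-to-peak) with round-half-up quantization; the
    scale and metadata are stored as JSON in the TIFF description tag so the
    physical values are recoverable to within one quantization step.
    """
    path = Path(path)
    data = m.data
    if not np.all(np.isfinite(data)):
        raise ValueError("micrograph contains NaN/inf pixels; refusing to export")
    vmax = 1.0 if m.kind == KIND_NOAS2 else (float(data.max()) if data.size else 0.0)
    scale = 65535.0 / vmax if vmax > 0 else 0.0
    pixels = np.floor(data * scale + 0.5).astype(np.uint16)  # round half up
    desc = json.dumps(
        {
            "vmax": vmax,
            "wavenumber_cm1": m.wavenumber,
            "step_size_um": m.step_size_um,
            "kind": m.kind,
        }
    )
    tifffile.imwrite(path, pixels, description=desc)
    return path


def import_micrograph_tiff(path) -> Micrograph:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise FormatError(f"{path}: missing description tag with scaling metadata")
        meta = json.loads(desc.value)
    data = pixels.astype(float) * (meta["vmax"] / 65535.0)
    return Micrograph(
        data=data,
        wavenumber=float(meta["wavenumber_cm1"]),
        step_size_um=float(meta["step_size_um"]),
        kind=str(meta["kind"]),
    )


# -- spectra CSV -----------------------------------------------------------

_ID_COLS = ["adipocyte_id", "mouse_id", "group", "stage", "qc_outlier"]


def _wavenumber_col(v: float) -> str:
    return format(v, ".10g")


def spectra_to_csv(ds: SpectralDataset, path) -> Path:
    """One row per spectrum: identifier columns then one column per wavenumber."""
    path = Path(path)
    df = ds.meta.copy()
    df.insert(3, "stage", ds.stage.name)
    cols = [_wavenumber_col(v) for v in ds.grid.values]
    spec = pd.DataFrame(ds.values, columns=cols)
    pd.concat([df[_ID_COLS], spec], axis=1).to_csv(path, index=False)
    return path


def spectra_from_csv(path) -> SpectralDataset:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _ID_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing identifier columns {missing}")
    wl_cols = [c for c in df.columns if c not in _ID_COLS]
    if not wl_cols:
        raise FormatError(f"{path}: no wavenumber columns found")
    try:
        values_cm1 = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber column: {exc}") from exc
    stages = df["stage"].unique()
    if len(stages) != 1:
        raise FormatError(f"{path}: expected a single stage, found {list(stages)}")
    grid = WavenumberGrid(values_cm1)
    meta = df[["adipocyte_id", "mouse_id", "group", "qc_outlier"]].copy()
    meta["adipocyte_id"] = meta["adipocyte_id"].astype(str)
    meta["mouse_id"] = meta["mouse_id"].astype(str)
    meta["qc_outlier"] = meta["qc_outlier"].astype(bool)
    values = df[wl_cols].to_numpy(dtype=float)
    if values.shape[1] != len(grid):
        raise FormatError(f"{path}: spectral column count does not match grid")
    return SpectralDataset(values, meta, grid, Stage[str(stages[0])])
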