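"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .constants import MIN_TRANSIENT_SAMPLES
from .grid import WavenumberGrid

GROUP_INFLAMED = "inflamed"
GROUP_NON_INFLAMED = "non_inflamed"


def validate_transient(samples: np.ndarray) -> np.ndarray:
    """Check a single optoacoustic transient (mV samples) and return it as float array.

    A valid transient has at least 400 samples, so that both the DC window
    (samples 1..176) and the energy window (samples 176..400) exist, and
    contains only finite values.
    """
    t = np.asarray(samples, dtype=float)
    if t.ndim != 1:
        raise ValueError("transient must be 1-D")
    if t.size < MIN_TRANSIENT_SAMPLES:
        raise ValueError(
            f"transient has {t.size} samples; at least {MIN_TRANSIENT_SAMPLES} are "
            "required so the DC window (1..176) and energy window (176..400) exist"
        )
    if not np.all(np.isfinite(t)):
        raise ValueError("transient contains non-finite values")
    return t


@dataclass
class ScanCube:
    """Raster-scan dataset: one transient per (row, col, wavenumber).

    ``transients`` has shape (rows, cols, n_wavenumbers, n_samples), values
    in mV.  ``step_size_um`` is the raster step.
    """

    transients: np.ndarray
    grid: WavenumberGrid
    step_size_um: float = 5.0
    n_averages: int = 50
    subject_id: str = ""
    acquired: str = ""

    def __post_init__(self):
        t = np.asarray(self.transients, dtype=float)
        if t.ndim != 4:
            raise ValueError("transients must have shape (rows, cols, n_wavenumbers, n_samples)")
        if t.shape[2] != len(self.grid):
            raise ValueError(
                f"wavenumber axis ({t.shape[2]}) does not match grid length ({len(self.grid)})"
            )
        if t.shape[3] < MIN_TRANSIENT_SAMPLES:
            raise ValueError(
                f"transients have {t.shape[3]} samples; at least "
                f"{MIN_TRANSIENT_SAMPLES} required (DC window 1..176, energy window 176..400)"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("scan cube contains non-finite samples")
        if not self.step_size_um > 0:
            raise ValueError("step_size_um must be positive")
        self.transients = t

    @property
    def shape(self):
        return self.transients.shape

    def transient(self, row: int, col: int, wavenumber: float) -> np.ndarray:
        return self.transients[row, col, self.grid.index_of(wavenumber)]


KIND_RAW_PTP = "raw-ptp"
KIND_NOAS2 = "NOAS2"


@dataclass
class Micrograph:
    """Single-wavenumber 2-D amplitude map.

    ``kind`` distinguishes raw peak-to-peak maps (mV, non-negative) from
    NOAS^2 maps (squared, field-of-view normalized, in [0, 1]).
    """

    data: np.ndarray
    wavenumber: float
    step_size_um: float = 5.0
    kind: str = KIND_RAW_PTP

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("micrograph data must be 2-D")
        if not np.all(np.isfinite(d)):
            raise ValueError("micrograph contains non-finite pixels")
        if self.kind == KIND_RAW_PTP and d.size and d.min() < 0:
            raise ValueError("raw peak-to-peak map must be non-negative")
        if self.kind == KIND_NOAS2 and d.size and (d.min() < 0 or d.max() > 1 + 1e-12):
            raise ValueError("NOAS2 map values must lie in [0, 1]")
        self.data = d

    @property
    def shape(self):
        return self.data.shape


class Stage(enum.IntEnum):
    """Pre-processing stages of an adipocyte spectrum, in pipeline order.

    The rank encodes the mandatory order: wavenumber-shift correction, then
    laser-profile correction, then L1 normalization, then standardization.
    Optional stages may be skipped, but applying a stage out of order raises.
    """

    RAW_PTP = 0
    RAW_SE = 1
    SHIFT_CORRECTED = 2
    CORRECTED = 3
    NORMALIZED = 4
    STANDARDIZED = 5


def require_stage(current: Stage, allowed_max: Stage, op: str) -> None:
    if current > allowed_max:
        raise ValueError(
            f"{op}: spectra are at stage {current.name}, which is past "
            f"{allowed_max.name}; pipeline stages must be applied in order"
        )


@dataclass
class SpectrumRecord:
    """One adipocyte spectrum aligned to a wavenumber grid."""

    adipocyte_id: str
    mouse_id: str
    group: str
    spectrum: np.ndarray
    grid: WavenumberGrid
    stage: Stage = Stage.RAW_SE
    qc_outlier: bool = False

    def __post_init__(self):
        s = np.asarray(self.spectrum, dtype=float)
        if s.shape != (len(self.grid),):
            raise ValueError("spectrum length must equal grid length")
        if not self.mouse_id or not self.group:
            raise ValueError("mouse_id and group must be non-empty")
        if self.stage == Stage.NORMALIZED and abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1")
        self.spectrum = s

    def with_spectrum(self, spectrum: np.ndarray, stage: Stage) -> "SpectrumRecord":
        return replace(self, spectrum=np.asarray(spectrum, dtype=float), stage=stage)


@dataclass
class SpectralDataset:
    """Matrix of adipocyte spectra sharing one grid, with per-spectrum metadata.

    ``values`` has shape (n_spectra, n_wavenumbers); ``meta`` is a DataFrame
    with columns adipocyte_id, mouse_id, group, qc_outlier.
    """

    values: np.ndarray
    meta: pd.DataFrame
    grid: WavenumberGrid
    stage: Stage = Stage.RAW_SE

    _META_COLS = ("adipocyte_id", "mouse_id", "group", "qc_outlier")

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.grid):
            raise ValueError("values must have shape (n_spectra, len(grid))")
        missing = [c for c in self._META_COLS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")
        if len(self.meta) != v.shape[0]:
            raise ValueError("meta row count must match number of spectra")
        if (self.meta["mouse_id"].astype(str) == "").any():
            raise ValueError("every spectrum needs a non-empty mouse_id")
        self.values = v
        self.meta = self.meta.reset_index(drop=True)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: list[SpectrumRecord]) -> "SpectralDataset":
        if not records:
            raise ValueError("need at least one record")
        grid = records[0].grid
        stage = records[0].stage
        for r in records:
            if r.grid != grid:
                raise ValueError("all records must share a single grid")
            if r.stage != stage:
                raise ValueError("all records must share one stage")
        values = np.vstack([r.spectrum for r in records])
        meta = pd.DataFrame(
            {
                "adipocyte_id": [r.adipocyte_id for r in records],
                "mouse_id": [r.mouse_id for r in records],
                "group": [r.group for r in records],
                "qc_outlier": [r.qc_outlier for r in records],
            }
        )
        return cls(values, meta, grid, stage)

    def records(self) -> list[SpectrumRecord]:
        return [
            SpectrumRecord(
                adipocyte_id=str(row.adipocyte_id),
                mouse_id=str(row.mouse_id),
                group=str(row.group),
                spectrum=self.values[i],
                grid=self.grid,
                stage=self.stage,
                qc_outlier=bool(row.qc_outlier),
            )
            for i, row in enumerate(self.meta.itertuples(index=False))
        ]

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def mouse_ids(self) -> np.ndarray:
        return self.meta["mouse_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.meta["group"].to_numpy()

    def mouse_counts(self) -> pd.Series:
        return self.meta["mouse_id"].value_counts()

    def retained(self) -> "SpectralDataset":
        """Subset of spectra not flagged as outliers."""
        keep = ~self.meta["qc_outlier"].to_numpy(dtype=bool)
        return self.subset(keep)

    def subset(self, mask) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(
            self.values[mask], self.meta.loc[mask].reset_index(drop=True), self.grid, self.stage
        )

    def with_values(self, values: np.ndarray, stage: Optional[Stage] = None) -> "SpectralDataset":
        return SpectralDataset(
            values, self.meta.copy(), self.grid, self.stage if stage is None else stage
        )
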