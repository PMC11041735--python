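"""Per-adipocyte spectrum extraction and pre-processing.

From each 400-sample transient two summaries are available: the peak-to-peak
amplitude and the signal energy, the sum of squared DC-corrected samples over
the fixed energy window (samples 176..400, 1-based; the DC offset is the
mean of the first 176 samples, which precede the acoustic arrival).

Signal-energy spectra are then pre-processed in a fixed order, enforced via
stage tags: (1) wavenumber-shift correction in the C-H stretching band,
(2) division by a broadband carbon-tape reference spectrum to cancel the
laser emission profile, (3) L1 normalization to unit total spectral energy,
(4) outlier removal (density-based local outlier factor plus wavenumber-wise
thresholding), (5) weighted per-wavenumber standardization with per-mouse
inverse-count weights.  Optional stages may be skipped; applying one out of
order is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import LocalOutlierFactor

from .constants import MIN_TRANSIENT_SAMPLES, dc_slice, energy_slice
from .containers import (
    SpectralDataset,
    SpectrumRecord,
    Stage,
    require_stage,
    validate_transient,
)
from .grid import BAND_A, WavenumberGrid

# -- transient summaries ---------------------------------------------------

def dc_offset(transient: np.ndarray) -> float:
    """DC offset (mV): mean of the first 176 samples (no acoustic signal yet)."""
    t = np.asarray(transient, dtype=float)
    if t.size < dc_slice().stop:
        raise ValueError(f"transient too short for the DC window (need {dc_slice().stop})")
    return float(t[dc_slice()].mean())


def signal_energy(transient: np.ndarray) -> float:
    """Signal energy (mV^2): sum of squared DC-removed samples 176..400."""
    t = np.asarray(transient, dtype=float)
    if t.size < MIN_TRANSIENT_SAMPLES:
        raise ValueError(
            f"transient too short for the energy window (need {MIN_TRANSIENT_SAMPLES})"
        )
    dc = dc_offset(t)
    window = t[energy_slice()] - dc
    return float(np.sum(window**2))


def _spectrum_from_transients(
    transients: np.ndarray, grid: WavenumberGrid, summary, stage: Stage, **ids
) -> SpectrumRecord:
    t = np.asarray(transients, dtype=float)
    if t.ndim != 2 or t.shape[0] != len(grid):
        raise ValueError(
            f"need one transient per grid wavenumber: got {t.shape[0]} for {len(grid)}"
        )
    for row in t:
        validate_transient(row)
    values = np.array([summary(row) for row in t])
    return SpectrumRecord(spectrum=values, grid=grid, stage=stage, **ids)


def ptp_spectrum(
    transients: np.ndarray,
    grid: WavenumberGrid,
    adipocyte_id: str = "",
    mouse_id: str = "unknown",
    group: str = "unknown",
) -> SpectrumRecord:
    """Peak-to-peak amplitude spectrum from per-wavenumber transients."""
    return _spectrum_from_transients(
        transients,
        grid,
        lambda t: float(t.max() - t.min()),
        Stage.RAW_PTP,
        adipocyte_id=adipocyte_id,
        mouse_id=mouse_id,
        group=group,
    )


def se_spectrum(
    transients: np.ndarray,
    grid: WavenumberGrid,
    adipocyte_id: str = "",
    mouse_id: str = "unknown",
    group: str = "unknown",
) -> SpectrumRecord:
    """Signal-energy spectrum from per-wavenumber transients."""
    return _spectrum_from_transients(
        transients,
        grid,
        signal_energy,
        Stage.RAW_SE,
        adipocyte_id=adipocyte_id,
        mouse_id=mouse_id,
        group=group,
    )


# -- corrections -----------------------------------------------------------

@dataclass(frozen=True)
class LaserReference:
    """Carbon-tape optoacoustic spectrum: the laser emission-intensity profile."""

    spectrum: np.ndarray
    grid: WavenumberGrid

    def __post_init__(self):
        s = np.asarray(self.spectrum, dtype=float)
        if s.shape != (len(self.grid),):
            raise ValueError("reference length must match its grid")
        object.__setattr__(self, "spectrum", s)


def correct_laser_profile(rec: SpectrumRecord, ref: LaserReference) -> SpectrumRecord:
    """Divide a spectrum by the carbon-tape reference, wavenumber by wavenumber."""
    require_stage(rec.stage, Stage.SHIFT_CORRECTED, "correct_laser_profile")
    if rec.grid != ref.grid:
        raise ValueError("spectrum and laser reference must share a grid")
    eps = 1e-12 * float(np.max(ref.spectrum))
    low = ref.spectrum <= eps
    if low.any():
        w = rec.grid.values[low][0]
        raise ValueError(f"laser reference is non-positive at {w} cm^-1")
    return rec.with_spectrum(rec.spectrum / ref.spectrum, Stage.CORRECTED)


def correct_wavenumber_shift(
    rec: SpectrumRecord,
    measured_grid: np.ndarray,
    nominal_grid: np.ndarray | None = None,
) -> SpectrumRecord:
    """Re-interpolate the C-H stretching band onto the nominal wavenumbers.

    The laser showed consistent tuning errors confined to the 2932-2772
    cm^-1 band for some tissues; the fingerprint band is left untouched.
    Values outside the measured range take the nearest measured value.
    """
    require_stage(rec.stage, Stage.RAW_SE, "correct_wavenumber_shift")
    band = rec.grid.band_mask(BAND_A)
    nominal = rec.grid.values[band] if nominal_grid is None else np.asarray(nominal_grid)
    measured = np.asarray(measured_grid, dtype=float)
    if measured.shape != nominal.shape:
        raise ValueError("measured grid must match the band's nominal grid in length")
    d = np.diff(measured)
    if measured.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("measured grid must be strictly monotone")
    values = rec.spectrum[band]
    order = np.argsort(measured)
    corrected = np.interp(nominal, measured[order], values[order])
    out = rec.spectrum.copy()
    out[band] = corrected
    return rec.with_spectrum(out, Stage.SHIFT_CORRECTED)


# -- normalization ----------------------------------------------------------

def l1_normalize(obj):
    """Scale spectra to unit total spectral energy (sum of entries = 1).

    Accepts a :class:`SpectrumRecord` or a :class:`SpectralDataset`.  Scale
    invariance of this step is what cancels day-to-day laser power and
    optoacoustic conversion-efficiency fluctuations.
    """
    if isinstance(obj, SpectralDataset):
        require_stage(obj.stage, Stage.CORRECTED, "l1_normalize")
        sums = obj.values.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("every spectrum must have a positive sum")
        return obj.with_values(obj.values / sums[:, None], Stage.NORMALIZED)
    rec: SpectrumRecord = obj
    require_stage(rec.stage, Stage.CORRECTED, "l1_normalize")
    total = rec.spectrum.sum()
    if total <= 0:
        raise ValueError("spectrum sum must be positive for L1 normalization")
    return rec.with_spectrum(rec.spectrum / total, Stage.NORMALIZED)


# -- outlier removal ---------------------------------------------------------

@dataclass(frozen=True)
class OutlierConfig:
    n_neighbors: int = 20
    contamination: float = 0.1
    threshold_sd: float = 6.0


@dataclass
class OutlierReport:
    n_total: int
    n_removed_lof: int
    n_removed_threshold: int
    retention: float


def detect_outliers(
    ds: SpectralDataset, cfg: OutlierConfig | None = None
) -> tuple[np.ndarray, OutlierReport]:
    """Flag artifact spectra; returns a keep-mask and a retention report.

    A spectrum is removed if the local outlier factor flags it (density-based,
    ``n_neighbors`` neighbors, expected ``contamination`` fraction) or if any
    wavenumber value lies more than ``threshold_sd`` standard deviations from
    that wavenumber's median.
    """
    cfg = cfg or OutlierConfig()
    n = len(ds)
    if n < 10:
        raise ValueError("outlier detection needs at least 10 spectra")
    if n <= cfg.n_neighbors:
        raise ValueError(
            f"outlier detection needs more spectra ({n}) than neighbors ({cfg.n_neighbors})"
        )
    lof = LocalOutlierFactor(n_neighbors=cfg.n_neighbors, contamination=cfg.contamination)
    lof_keep = lof.fit_predict(ds.values) == 1
    med = np.median(ds.values, axis=0)
    sd = ds.values.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    thr_keep = ~(np.abs(ds.values - med) > cfg.threshold_sd * sd).any(axis=1)
    keep = lof_keep & thr_keep
    report = OutlierReport(
        n_total=n,
        n_removed_lof=int((~lof_keep).sum()),
        n_removed_threshold=int((~thr_keep).sum()),
        retention=float(keep.mean()),
    )
    return keep, report


def apply_outlier_mask(ds: SpectralDataset, keep: np.ndarray) -> SpectralDataset:
    """Record the QC flags on the dataset (spectra are kept, flagged)."""
    meta = ds.meta.copy()
    meta["qc_outlier"] = ~np.asarray(keep, dtype=bool)
    return SpectralDataset(ds.values, meta, ds.grid, ds.stage)


# -- standardization ---------------------------------------------------------

@dataclass
class StandardizationModel:
    """Weighted per-wavenumber location/scale model.

    Weights are the inverse spectrum count of each spectrum's mouse, so
    heavily sampled tissues do not dominate the location and scale.  The
    standard deviation uses the population convention (divide by the sum of
    weights).
    """

    mean: np.ndarray
    sd: np.ndarray
    grid: WavenumberGrid
    mouse_weights: dict[str, float]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


def spectrum_weights(ds: SpectralDataset) -> np.ndarray:
    counts = ds.mouse_counts()
    return np.array([1.0 / counts[m] for m in ds.mouse_ids])


def fit_standardization(ds: SpectralDataset) -> StandardizationModel:
    """Fit the weighted standardization on a normalized dataset."""
    require_stage(ds.stage, Stage.NORMALIZED, "fit_standardization")
    if ds.stage != Stage.NORMALIZED:
        raise ValueError("standardization must be fitted on L1-normalized spectra")
    if len(ds) < 2:
        raise ValueError("standardization needs at least two spectra")
    w = spectrum_weights(ds)
    mean = np.average(ds.values, axis=0, weights=w)
    var = np.average((ds.values - mean) ** 2, axis=0, weights=w)
    if np.any(var <= 0):
        bad = ds.grid.values[np.argmin(var)]
        raise ValueError(f"zero weighted variance at {bad} cm^-1; cannot standardize")
    counts = ds.mouse_counts()
    return StandardizationModel(
        mean=mean,
        sd=np.sqrt(var),
        grid=ds.grid,
        mouse_weights={m: 1.0 / c for m, c in counts.items()},
    )


def apply_standardization(
    model: StandardizationModel, ds: SpectralDataset
) -> SpectralDataset:
    require_stage(ds.stage, Stage.NORMALIZED, "apply_standardization")
    if ds.grid != model.grid:
        raise ValueError("dataset grid does not match the standardization model")
    return ds.with_values(model.transform(ds.values), Stage.STANDARDIZED)
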