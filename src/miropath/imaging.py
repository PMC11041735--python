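"""Micrograph formation and contrast metrics.

A micrograph assigns each raster position the peak-to-peak amplitude of its
optoacoustic transient at one wavenumber.  For display and segmentation the
map is squared and normalized by its field-of-view maximum (NOAS^2), which
compresses the background and enhances structural definition.  Contrast-to-
noise ratio follows CNR = (ptp_A - ptp_B) / noise_ptp with the dark noise of
the detection chain in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .containers import KIND_NOAS2, KIND_RAW_PTP, Micrograph, ScanCube


def ptp_amplitude(transient: np.ndarray) -> float:
    """Peak-to-peak amplitude (mV) over the full transient."""
    t = np.asarray(transient, dtype=float)
    if t.size == 0:
        raise ValueError("empty transient")
    return float(t.max() - t.min())


def build_micrograph(cube: ScanCube, wavenumber: float) -> Micrograph:
    """Raw peak-to-peak amplitude map at one wavenumber of the cube's grid."""
    k = cube.grid.index_of(wavenumber)
    t = cube.transients[:, :, k, :]
    data = t.max(axis=-1) - t.min(axis=-1)
    return Micrograph(
        data=np.asarray(data, dtype=float),
        wavenumber=float(cube.grid.values[k]),
        step_size_um=cube.step_size_um,
        kind=KIND_RAW_PTP,
    )


def normalize_noas2(m: Micrograph) -> Micrograph:
    """Normalized squared intensity: ptp^2 / max(ptp^2) over the FOV."""
    if m.kind != KIND_RAW_PTP:
        raise ValueError("normalize_noas2 expects a raw peak-to-peak map")
    sq = m.data.astype(float) ** 2
    peak = sq.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero map")
    return Micrograph(sq / peak, m.wavenumber, m.step_size_um, kind=KIND_NOAS2)


@dataclass(frozen=True)
class CNRReport:
    point_a: tuple[int, int]
    point_b: tuple[int, int]
    ptp_a_mv: float
    ptp_b_mv: float
    noise_ptp_mv: float

    @property
    def cnr(self) -> float:
        return (self.ptp_a_mv - self.ptp_b_mv) / self.noise_ptp_mv

    @property
    def cnr_integer(self) -> int:
        """The ratio as printed, i.e. the integer part of the float CNR."""
        return int(self.cnr)


def cnr(
    m: Micrograph,
    point_a: tuple[int, int],
    point_b: tuple[int, int],
    noise_ptp_mv: float,
) -> CNRReport:
    """Contrast-to-noise ratio between a sample pixel and a background pixel."""
    if m.kind != KIND_RAW_PTP:
        raise ValueError("CNR is defined on the raw peak-to-peak map")
    if noise_ptp_mv <= 0:
        raise ValueError("noise_ptp_mv must be positive")
    rows, cols = m.shape
    for name, (r, c) in (("A", point_a), ("B", point_b)):
        if not (0 <= r < rows and 0 <= c < cols):
            raise IndexError(f"point {name} {(r, c)} outside map of shape {m.shape}")
    return CNRReport(
        point_a=tuple(point_a),
        point_b=tuple(point_b),
        ptp_a_mv=float(m.data[point_a]),
        ptp_b_mv=float(m.data[point_b]),
        noise_ptp_mv=float(noise_ptp_mv),
    )


def cnr_from_values(ptp_a_mv: float, ptp_b_mv: float, noise_ptp_mv: float) -> CNRReport:
    """CNR directly from measured amplitudes (region means or single pixels)."""
    if noise_ptp_mv <= 0:
        raise ValueError("noise_ptp_mv must be positive")
    return CNRReport((-1, -1), (-1, -1), float(ptp_a_mv), float(ptp_b_mv), float(noise_ptp_mv))


def merge_channels(
    maps: list[Micrograph], channels: list[str] | None = None
) -> np.ndarray:
    """Merge up to three NOAS^2 maps into an RGB composite in [0, 1]."""
    if not 1 <= len(maps) <= 3:
        raise ValueError("merge_channels takes one to three maps")
    channels = channels or ["red", "green", "blue"][: len(maps)]
    if len(channels) != len(maps):
        raise ValueError("one channel name per map")
    shape = maps[0].shape
    rgb = np.zeros(shape + (3,), dtype=float)
    index = {"red": 0, "green": 1, "blue": 2}
    for m, ch in zip(maps, channels):
        if m.shape != shape:
            raise ValueError("all maps must share a shape")
        if m.kind != KIND_NOAS2:
            raise ValueError("merge_channels expects NOAS2-normalized maps")
        rgb[..., index[ch]] = m.data
    return rgb


#: structural-similarity parameters used throughout (uniform window)
SSIM_PARAMS = dict(win_size=7, K1=0.01, K2=0.03, gaussian_weights=False)


def ssim_index(m1: Micrograph, m2: Micrograph, data_range: float = 1.0) -> float:
    """Structural similarity between two equally shaped micrographs.

    Computed with a 7x7 uniform window and the standard stabilization
    constants (K1=0.01, K2=0.03); ``data_range`` defaults to 1, appropriate
    for NOAS^2 maps.
    """
    if m1.shape != m2.shape:
        raise ValueError("micrographs must share a shape")
    return float(
        structural_similarity(m1.data, m2.data, data_range=data_range, **SSIM_PARAMS)
    )
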