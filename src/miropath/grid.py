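"""Wavenumber grid of the two quantum-cascade-laser bands.

The instrument tunes over two disjoint mid-infrared bands, recorded in
acquisition order from high to low wavenumber: band A covers the C-H
stretching region (2932-2772 cm^-1) and band B the fingerprint region
(1736-910 cm^-1), both at 4 cm^-1 steps.  The default grid is anchored at
x.55 cm^-1 values matching the instrument wavenumber tables, giving
41 + 207 = 248 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WAVENUMBER_MAX, WAVENUMBER_MIN

BAND_A = "A"
BAND_B = "B"

_DEFAULT_A = (2932.55, 2772.55)
_DEFAULT_B = (1736.55, 912.55)
_DEFAULT_STEP = 4.0


@dataclass(frozen=True)
class WavenumberGrid:
    """Ordered wavenumbers (cm^-1) with per-value band labels.

    Values must be strictly monotone within each band and lie inside the
    laser's tuning range.  Equality and hashing are by value.
    """

    values: np.ndarray
    band_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("grid values must be a non-empty 1-D array")
        labels = self.band_labels
        if labels is None:
            labels = np.where(values > 2000.0, BAND_A, BAND_B)
        labels = np.asarray(labels, dtype="U1")
        if labels.shape != values.shape:
            raise ValueError("band_labels must match values in shape")
        if not np.all((values >= WAVENUMBER_MIN) & (values <= WAVENUMBER_MAX)):
            raise ValueError(
                f"wavenumbers must lie within [{WAVENUMBER_MIN}, {WAVENUMBER_MAX}] cm^-1"
            )
        for band in np.unique(labels):
            v = values[labels == band]
            d = np.diff(v)
            if v.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"wavenumbers must be strictly monotone within band {band!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_labels", labels)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WavenumberGrid)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.band_labels, other.band_labels)
        )

    def __hash__(self) -> int:
        return hash((self.values.tobytes(), self.band_labels.tobytes()))

    def index_of(self, wavenumber: float, atol: float = 1e-6) -> int:
        """Index of ``wavenumber`` in the grid, or ``KeyError`` listing choices."""
        hits = np.flatnonzero(np.isclose(self.values, wavenumber, atol=atol))
        if hits.size == 0:
            raise KeyError(
                f"wavenumber {wavenumber} cm^-1 not in grid; available: "
                f"{np.array2string(self.values, threshold=20)}"
            )
        return int(hits[0])

    def band_mask(self, band: str) -> np.ndarray:
        return self.band_labels == band

    def subset(self, indices) -> "WavenumberGrid":
        idx = np.asarray(indices)
        return WavenumberGrid(self.values[idx], self.band_labels[idx])

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """Full two-band acquisition grid (248 points, 4 cm^-1 steps)."""
        a = np.arange(_DEFAULT_A[0], _DEFAULT_A[1] - 1e-9, -_DEFAULT_STEP)
        b = np.arange(_DEFAULT_B[0], _DEFAULT_B[1] - 1e-9, -_DEFAULT_STEP)
        values = np.concatenate([a, b])
        labels = np.array([BAND_A] * a.size + [BAND_B] * b.size)
        return cls(values, labels)

    @classmethod
    def single(cls, wavenumber: float) -> "WavenumberGrid":
        """One-wavenumber grid, convenient for single-channel imaging."""
        return cls(np.array([float(wavenumber)]))
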