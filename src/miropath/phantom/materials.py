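"""Material absorption spectra for the tissue phantom.

Each material is a sum of Gaussian vibrational peaks over a constant broad
baseline (water and non-resonant background absorption).  Amplitudes are in
the same units as rendered peak-to-peak amplitudes (mV at the reference
excitation fluence), so the library is calibrated directly against the
contrast values the imaging system reports:

* adipocyte lipid at 2852 cm^-1 (CH2 symmetric stretch): 460 mV, the
  maximum over the C-H stretching band;
* extracellular matrix at 1550 cm^-1 (amide II): 82:1 contrast-to-noise
  over the 12 mV background at 1.3 mV dark noise;
* adipocyte-interior protein: under 8:1 CNR at 1550 cm^-1;
* crown-like-structure ring: 1.5x the ECM spectrum;
* dying adipocytes: 0.8x the healthy adipocyte spectrum (20% lipid
  contrast deficit);
* small lipid-variant features: 0.90x adipocyte at 2852 cm^-1 and 1.17x
  at 1550 cm^-1, with an extra CH2/CH3-bending peak near 1473 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grid import WavenumberGrid

MATERIALS = (
    "lipid_adipocyte",
    "dying_adipocyte",
    "protein_ecm",
    "cls_ring",
    "lipid_variant_1473",
    "background",
)

#: broad baseline absorption common to all tissue materials, mV
BASELINE_MV = 12.0


@dataclass(frozen=True)
class GaussianPeak:
    center_cm1: float
    width_cm1: float
    amplitude: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.width_cm1 <= 0:
            raise ValueError("peak width must be positive")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((wavenumbers - self.center_cm1) ** 2) / (2.0 * self.width_cm1**2)
        )


@dataclass(frozen=True)
class MaterialSpectra:
    """Per-material peak lists plus constant offsets, evaluated lazily."""

    peaks: dict[str, tuple[GaussianPeak, ...]]
    offsets: dict[str, float] = field(default_factory=dict)

    def evaluate(self, material: str, grid: WavenumberGrid) -> np.ndarray:
        if material not in self.peaks:
            raise KeyError(f"unknown material {material!r}; have {sorted(self.peaks)}")
        w = grid.values
        out = np.full(w.shape, float(self.offsets.get(material, 0.0)))
        for p in self.peaks[material]:
            out += p.evaluate(w)
        return out

    def evaluate_all(self, grid: WavenumberGrid) -> dict[str, np.ndarray]:
        return {m: self.evaluate(m, grid) for m in self.peaks}

    def scaled(self, material: str, factor: float) -> tuple[tuple[GaussianPeak, ...], float]:
        peaks = tuple(
            GaussianPeak(p.center_cm1, p.width_cm1, p.amplitude * factor)
            for p in self.peaks[material]
        )
        return peaks, self.offsets.get(material, 0.0) * factor


def make_spectral_library(
    peak_config: dict[str, dict] | None = None,
) -> MaterialSpectra:
    """Build a material library from ``{material: {"peaks": [(c, w, a), ...], "offset": o}}``.

    With no argument, returns the calibrated default library.  Negative
    amplitudes are rejected by :class:`GaussianPeak`.
    """
    if peak_config is None:
        return default_library()
    peaks = {}
    offsets = {}
    for mat, cfg in peak_config.items():
        peaks[mat] = tuple(GaussianPeak(*p) for p in cfg.get("peaks", ()))
        offsets[mat] = float(cfg.get("offset", 0.0))
    return MaterialSpectra(peaks, offsets)


def _value_at(peaks: list[GaussianPeak], offset: float, w: float) -> float:
    return offset + sum(p.evaluate(np.array([w]))[0] for p in peaks)


def default_library(
    lipid_2852_mv: float = 460.0,
    background_mv: float = BASELINE_MV,
    ecm_cnr_1550: float = 82.0,
    adipocyte_cnr_1550: float = 6.0,
    dark_noise_ptp_mv: float = 1.3,
    cls_over_ecm: float = 1.5,
    dying_over_healthy: float = 0.8,
    p3_over_adipocyte_2852: float = 0.90,
    p3_over_adipocyte_1550: float = 1.17,
) -> MaterialSpectra:
    """Default calibrated library.

    Peak amplitudes at the calibration wavenumbers are solved exactly so that
    the evaluated spectra reproduce the target amplitudes and ratios listed in
    the module docstring, accounting for the baseline and neighboring-peak
    tails.
    """
    # adipocyte: lipid peaks; the 2852 amplitude is solved so the evaluated
    # value at 2852 equals lipid_2852_mv exactly
    adip = [
        GaussianPeak(2922.0, 14.0, 0.93 * lipid_2852_mv),  # CH2 asym stretch
        GaussianPeak(1740.0, 12.0, 0.26 * lipid_2852_mv),  # ester C=O
        GaussianPeak(1465.0, 14.0, 0.30 * lipid_2852_mv),  # CH2/CH3 bending
        GaussianPeak(1160.0, 25.0, 0.20 * lipid_2852_mv),  # C-O stretch
    ]
    # small amide contribution inside adipocytes (CNR < 8:1 at 1550)
    adip_1550 = background_mv + adipocyte_cnr_1550 * dark_noise_ptp_mv
    adip.append(
        GaussianPeak(
            1550.0, 20.0, adip_1550 - _value_at(adip, background_mv, 1550.0)
        )
    )
    adip.insert(
        0,
        GaussianPeak(
            2852.0, 12.0, lipid_2852_mv - _value_at(adip, background_mv, 2852.0)
        ),
    )

    # extracellular matrix: amide I and II over the baseline
    ecm = [GaussianPeak(1650.0, 25.0, 1.08 * ecm_cnr_1550 * dark_noise_ptp_mv)]
    ecm_1550 = background_mv + ecm_cnr_1550 * dark_noise_ptp_mv
    ecm.append(GaussianPeak(1550.0, 22.0, ecm_1550 - _value_at(ecm, background_mv, 1550.0)))

    lib = {
        "lipid_adipocyte": {"peaks": [(p.center_cm1, p.width_cm1, p.amplitude) for p in adip],
                            "offset": background_mv},
        "protein_ecm": {"peaks": [(p.center_cm1, p.width_cm1, p.amplitude) for p in ecm],
                        "offset": background_mv},
        "background": {"peaks": [], "offset": background_mv},
    }

    # dying adipocyte: uniform lipid-contrast deficit
    lib["dying_adipocyte"] = {
        "peaks": [(p.center_cm1, p.width_cm1, p.amplitude * dying_over_healthy) for p in adip],
        "offset": background_mv * dying_over_healthy,
    }
    # crown-like-structure ring: amide excess over ECM
    lib["cls_ring"] = {
        "peaks": [(p.center_cm1, p.width_cm1, p.amplitude * cls_over_ecm) for p in ecm],
        "offset": background_mv * cls_over_ecm,
    }

    # small lipid-variant features near adipocyte edges
    p3 = [
        GaussianPeak(p.center_cm1, p.width_cm1, p.amplitude * p3_over_adipocyte_2852)
        for p in adip
    ]
    p3_offset = background_mv * p3_over_adipocyte_2852
    p3.append(GaussianPeak(1473.0, 10.0, 0.12 * lipid_2852_mv))  # extra CH2/CH3 bending
    # solve the amide amplitude so the 1550 value is exactly 1.17x adipocyte
    target_1550 = p3_over_adipocyte_1550 * _value_at(adip, background_mv, 1550.0)
    p3.append(GaussianPeak(1550.0, 22.0, target_1550 - _value_at(p3, p3_offset, 1550.0)))
    lib["lipid_variant_1473"] = {
        "peaks": [(p.center_cm1, p.width_cm1, p.amplitude) for p in p3],
        "offset": p3_offset,
    }
    return make_spectral_library(lib)
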