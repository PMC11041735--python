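"""Synthetic per-adipocyte spectral cohorts with known ground truth.

Each mouse carries a smooth multiplicative tissue field (log-normal, with a
Gaussian correlation kernel across wavenumbers) that shifts all of its
adipocyte spectra together -- the mechanism behind the strong per-tissue
clustering the exploratory embedding shows on real data.  Individual cells
add a smaller smooth field, a white noise floor, and a scalar acquisition
power jitter that the L1 normalization later cancels.  Inflamed mice can be
given a mean shift of ``effect_size`` pooled-s.d. units (on the log scale)
at configured effect wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..containers import GROUP_INFLAMED, GROUP_NON_INFLAMED, SpectralDataset, Stage
from ..grid import WavenumberGrid
from .materials import MaterialSpectra, default_library
from .render import bipolar_pulse

#: default candidate effect positions (cm^-1): fingerprint-region
#: CH2/CH3-bending and C-O bands where inflamed and control adipocyte
#: spectra are most likely to differ
CANDIDATE_EFFECT_WAVENUMBERS = (
    1476.55,
    1340.55,
    1336.55,
    1332.55,
    1328.55,
    1324.55,
    1320.55,
    1312.55,
    1300.55,
    1036.55,
)


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    mouse_ids: list[str]
    groups: list[str]
    mouse_fields: np.ndarray  # (n_mice, n_wavenumbers) log-scale fields
    effect_indices: np.ndarray
    effect_log_shift: float
    base_spectrum: np.ndarray


def base_signal_energy_spectrum(
    grid: WavenumberGrid, spectra: MaterialSpectra | None = None
) -> np.ndarray:
    """Noise-free signal-energy spectrum of a pure adipocyte pixel (mV^2).

    Proportional to the squared lipid absorption spectrum; the constant is
    the energy of the unit peak-to-peak acoustic pulse.
    """
    spectra = spectra or default_library()
    pulse = bipolar_pulse()
    return spectra.evaluate("lipid_adipocyte", grid) ** 2 * float(np.sum(pulse**2))


def synthetic_psats_matrix(
    n_subjects: int = 17,
    n_components: int = 12,
    n_wavenumbers: int = 248,
    noise_variance_frac: float = 0.005,
    seed: int | None = None,
) -> np.ndarray:
    """Per-subject averaged spectra with an exact low-rank latent structure.

    Rows are linear combinations of ``n_components`` orthonormal basis
    spectra with equal-variance coefficients plus white residual noise
    contributing ``noise_variance_frac`` of the signal variance.  The
    coefficient matrix is column-centered and exactly orthogonalized so the
    mean-centered data carry ``n_components`` equal nonzero eigenvalues --
    i.e. the latent dimension is realized exactly, not just in expectation
    (with i.i.d. coefficients the smallest sample eigenvalue of so few
    subjects routinely falls below a 1% variance threshold and the rank is
    under-counted).
    """
    if n_components >= n_subjects:
        raise ValueError("need more subjects than latent components")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((n_wavenumbers, n_components)))
    coeff = rng.standard_normal((n_subjects, n_components))
    coeff = coeff - coeff.mean(axis=0)
    coeff, _ = np.linalg.qr(coeff)  # orthonormal columns, still column-centered
    coeff *= np.sqrt(n_subjects)
    x = coeff @ basis.T
    signal_var = np.sum((x - x.mean(axis=0)) ** 2)
    noise = rng.standard_normal((n_subjects, n_wavenumbers))
    noise -= noise.mean(axis=0)
    noise *= np.sqrt(noise_variance_frac * signal_var / np.sum(noise**2))
    return x + noise


def _smooth_cholesky(grid: WavenumberGrid, length_cm1: float) -> np.ndarray:
    w = grid.values
    k = np.exp(-((w[:, None] - w[None, :]) ** 2) / (2.0 * length_cm1**2))
    return np.linalg.cholesky(k + 1e-10 * np.eye(len(w)))


def make_spectral_cohort(
    cfg,
    seed: int | None = None,
    grid: WavenumberGrid | None = None,
    spectra: MaterialSpectra | None = None,
) -> tuple[SpectralDataset, CohortTruth]:
    """Generate raw signal-energy adipocyte spectra for a whole cohort.

    ``cfg`` is a :class:`~miropath.phantom.scene.CohortConfig`; ``seed``
    overrides ``cfg.seed``.  Returns the dataset (stage ``RAW_SE``) and the
    ground-truth record of every per-mouse draw.
    """
    grid = grid or WavenumberGrid.default()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base = base_signal_energy_spectrum(grid, spectra)
    n_wav = len(grid)
    chol = _smooth_cholesky(grid, cfg.corr_length_cm1)

    eff_idx = np.array(
        [grid.index_of(w) for w in cfg.effect_wavenumbers], dtype=int
    )
    pooled_sd = float(
        np.sqrt(cfg.mouse_effect_sd**2 + cfg.cell_effect_sd**2 + cfg.white_noise_sd**2)
    )
    log_shift = cfg.effect_size * pooled_sd

    values, meta_rows = [], []
    mouse_ids, groups, fields = [], [], []
    plan = [
        (GROUP_NON_INFLAMED, cfg.n_non_inflamed, cfg.spectra_per_mouse_non_inflamed),
        (GROUP_INFLAMED, cfg.n_inflamed, cfg.spectra_per_mouse_inflamed),
    ]
    for group, n_mice, n_cells in plan:
        for m in range(n_mice):
            mouse_id = f"{group}-m{m:02d}"
            field = cfg.mouse_effect_sd * (chol @ rng.standard_normal(n_wav))
            if group == GROUP_INFLAMED and log_shift > 0 and eff_idx.size:
                field = field.copy()
                field[eff_idx] += log_shift
            cell_smooth = cfg.cell_effect_sd * (chol @ rng.standard_normal((n_wav, n_cells))).T
            cell_white = cfg.white_noise_sd * rng.standard_normal((n_cells, n_wav))
            power = np.exp(rng.normal(0.0, cfg.power_jitter_sd, (n_cells, 1)))
            cells = base * np.exp(field + cell_smooth + cell_white) * power
            values.append(cells)
            for c in range(n_cells):
                meta_rows.append(
                    dict(
                        adipocyte_id=f"{mouse_id}-a{c:03d}",
                        mouse_id=mouse_id,
                        group=group,
                        qc_outlier=False,
                    )
                )
            mouse_ids.append(mouse_id)
            groups.append(group)
            fields.append(field)

    ds = SpectralDataset(
        np.vstack(values), pd.DataFrame(meta_rows), grid, Stage.RAW_SE
    )
    truth = CohortTruth(
        mouse_ids=mouse_ids,
        groups=groups,
        mouse_fields=np.vstack(fields),
        effect_indices=eff_idx,
        effect_log_shift=log_shift,
        base_spectrum=base,
    )
    return ds, truth
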