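"""Group comparison between inflamed and non-inflamed adipocyte spectra.

Adipocyte spectra from one tissue are not statistically independent: the
exploratory embedding of standardized spectra clusters strongly by mouse.
The testing unit is therefore the per-subject averaged tissue spectrum
(psaTS, one mean spectrum per mouse).  For every wavenumber a two-sided
Welch t-test compares the group means; the Bonferroni family size is not
the raw wavenumber count but the effective number of degrees of freedom:
the number of principal components of the psaTS matrix needed to reach 99%
explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .containers import GROUP_INFLAMED, GROUP_NON_INFLAMED, SpectralDataset, Stage
from .grid import WavenumberGrid


# -- clustering diagnostic --------------------------------------------------

@dataclass
class ClusterDiagnostic:
    silhouette_by_mouse: float
    n_mice: int
    embedding: np.ndarray | None = None


def cluster_diagnostic(
    ds: SpectralDataset, compute_embedding: bool = False, random_state: int = 0
) -> ClusterDiagnostic:
    """Quantify per-mouse clustering of standardized spectra.

    The decision statistic is the mean silhouette coefficient of mouse-ID
    labels in full spectral space; a positive value indicates tissue-level
    dependence, in which case inference must use per-subject averages.  A
    2-D embedding (UMAP if installed) can be attached for visualization
    only -- stochastic embeddings are not a test surface.
    """
    if ds.stage != Stage.STANDARDIZED:
        raise ValueError("cluster diagnostic expects standardized spectra")
    labels = ds.mouse_ids
    if np.unique(labels).size < 2:
        raise ValueError("need at least two mice for the clustering diagnostic")
    score = float(silhouette_score(ds.values, labels))
    embedding = None
    if compute_embedding:
        try:
            import umap

            embedding = umap.UMAP(n_components=2, random_state=random_state).fit_transform(
                ds.values
            )
        except ImportError:
            embedding = None
    return ClusterDiagnostic(score, int(np.unique(labels).size), embedding)


# -- per-subject averaging ---------------------------------------------------

@dataclass
class PsaTS:
    """Per-subject averaged tissue spectra: one row per mouse."""

    values: np.ndarray
    mouse_ids: list[str]
    groups: list[str]
    grid: WavenumberGrid

    def group_matrix(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        return self.values[mask]


def per_subject_average(ds: SpectralDataset) -> PsaTS:
    """Unweighted mean spectrum per mouse over retained spectra."""
    retained = ds.retained()
    mouse_ids = sorted(set(ds.mouse_ids))
    rows, groups = [], []
    for m in mouse_ids:
        mask = retained.mouse_ids == m
        if not mask.any():
            raise ValueError(f"mouse {m!r} has no retained spectra")
        rows.append(retained.values[mask].mean(axis=0))
        groups.append(str(retained.groups[mask][0]))
    return PsaTS(np.vstack(rows), mouse_ids, groups, ds.grid)


# -- Welch tests -------------------------------------------------------------

def welch_test(
    psa: PsaTS,
    group_a: str = GROUP_INFLAMED,
    group_b: str = GROUP_NON_INFLAMED,
) -> pd.DataFrame:
    """Wavenumber-wise two-sided Welch t-tests on the psaTS group means.

    Returns a DataFrame with columns wavenumber_cm1, t, df_welch, p_raw.
    """
    a = psa.group_matrix(group_a)
    b = psa.group_matrix(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least two mice for a Welch test")
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    return pd.DataFrame(
        {
            "wavenumber_cm1": psa.grid.values,
            "t": res.statistic,
            "df_welch": res.df,
            "p_raw": res.pvalue,
        }
    )


def effective_dof(psa: PsaTS, var_threshold: float = 0.99) -> int:
    """Effective degrees of freedom: principal components to reach the
    explained-variance threshold (inclusive) on the mean-centered psaTS
    matrix."""
    x = psa.values - psa.values.mean(axis=0)
    total = np.sum(x**2)
    if total <= 0:
        raise ValueError("psaTS matrix has zero variance")
    s = np.linalg.svd(x, compute_uv=False)
    ratios = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(ratios, var_threshold - 1e-12) + 1)


def bonferroni_adjust(p_raw: np.ndarray, n_c: int) -> np.ndarray:
    """Bonferroni correction with the effective family size: min(1, p * n_c)."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("raw p-values must lie in [0, 1]")
    if n_c < 1:
        raise ValueError("n_c must be at least 1")
    return np.minimum(1.0, p * n_c)


@dataclass
class WelchResult:
    table: pd.DataFrame  # wavenumber_cm1, t, df_welch, p_raw, p_adj
    n_c: int
    alpha: float = 0.05
    top: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def any_significant(self) -> bool:
        return bool((self.table["p_adj"] < self.alpha).any())


def run_group_comparison(
    ds: SpectralDataset,
    var_threshold: float = 0.99,
    alpha: float = 0.05,
    n_top: int = 10,
) -> WelchResult:
    """Full chain: per-subject average, Welch tests, PCA effective degrees of
    freedom, Bonferroni adjustment, and the ranked low-p wavenumber table.

    Ties in the ranked table are broken by wavenumber, descending.
    """
    psa = per_subject_average(ds)
    table = welch_test(psa)
    n_c = effective_dof(psa, var_threshold)
    table["p_adj"] = bonferroni_adjust(table["p_raw"].to_numpy(), n_c)
    ranked = table.sort_values(
        ["p_adj", "wavenumber_cm1"], ascending=[True, False]
    ).head(n_top)
    return WelchResult(table=table, n_c=n_c, alpha=alpha, top=ranked.reset_index(drop=True))


# -- spectral density ---------------------------------------------------------

@dataclass
class DensityHistogram:
    counts: dict[str, np.ndarray]  # group -> (n_wavenumbers, n_value_bins)
    value_edges: np.ndarray
    wavenumbers: np.ndarray

    def overlap(self, w_lo: float, w_hi: float) -> float:
        """Histogram-intersection overlap of the two groups in a wavenumber band."""
        (ca, cb) = (self.counts[g] for g in self.counts)
        mask = (self.wavenumbers >= w_lo) & (self.wavenumbers <= w_hi)
        a = ca[mask] / max(ca[mask].sum(), 1)
        b = cb[mask] / max(cb[mask].sum(), 1)
        return float(np.minimum(a, b).sum())


def spectral_density_hist(
    ds: SpectralDataset, value_bins: np.ndarray | None = None
) -> DensityHistogram:
    """Two-dimensional (wavenumber x standardized value) histograms per group."""
    if ds.stage != Stage.STANDARDIZED:
        raise ValueError("spectral density plot expects standardized spectra")
    if value_bins is None:
        lo, hi = float(ds.values.min()), float(ds.values.max())
        edges = np.linspace(lo, hi + 1e-9, 51)
    else:
        edges = np.asarray(value_bins)
    counts = {}
    for group in np.unique(ds.groups):
        sub = ds.values[ds.groups == group]
        if sub.size == 0:
            raise ValueError(f"group {group!r} is empty")
        counts[group] = np.vstack(
            [np.histogram(sub[:, j], bins=edges)[0] for j in range(sub.shape[1])]
        )
    return DensityHistogram(counts, edges, ds.grid.values)
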