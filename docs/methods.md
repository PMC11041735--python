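# Methods notes

This note records the models, calibrations and design choices behind
`miropath`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and index conventions

Each raster position and wavenumber yields a 400-sample transient (mV).
Windows are 1-based inclusive and defined once in `miropath.constants`:

* **DC window, samples 1–176** — before the acoustic arrival; the DC offset
  is their arithmetic mean.
* **Energy window, samples 176–400** — the signal energy is the sum of the
  225 squared, DC-removed samples. The one-sample overlap at 176 is kept
  as defined; the rendered pulse is zero there, so it has no numerical
  consequence in the phantom.

The wavenumber grid covers the laser's two bands in acquisition order
(high→low): 2932.55–2772.55 and 1736.55–912.55 cm⁻¹ at 4 cm⁻¹ steps
(41 + 207 = 248 points). The x.55 anchoring follows the instrument's
wavenumber tables; the grid is fully configurable, and the validity bound
(908–2933 cm⁻¹) leaves margin for the anchoring offset.

## Phantom generator

The generator produces what the analysis consumes — scenes, scan cubes and
spectral cohorts — with known ground truth. It **emulates**: adipocyte /
matrix / crown-like-structure (CLS) geometry at 5 µm step; the published
contrast ratios; bipolar transients with DC offset and dark noise;
per-mouse spectral random effects; optional group effects at chosen
wavenumbers. It does **not** emulate acoustic frequency response,
focusing/defocusing, water-band structure, polygonal cell shapes, or
spatially varying illumination, so passing tests demonstrate correctness of
the processing chain, not instrument realism.

### Material spectra

Materials are Gaussian-peak sums over a 12 mV broadband baseline, in units
of rendered peak-to-peak mV. Peak amplitudes at the calibration points are
solved exactly (accounting for neighbor-peak tails), so that:

* adipocyte lipid at 2852 cm⁻¹ = 460 mV, the band-A maximum;
* matrix (ECM) amide II gives 82:1 CNR over the 12 mV background at 1.3 mV
  noise; adipocyte-interior protein stays below 8:1;
* the CLS ring is exactly 1.5× the ECM spectrum; dying adipocytes are
  exactly 0.8× healthy (20 % lipid-contrast deficit, 50 % diameter);
* the small lipid-variant features are 0.90× adipocyte at 2852 cm⁻¹ and
  1.17× at 1550 cm⁻¹, with an extra 1473 cm⁻¹ bending peak.

### Scene geometry

At the measured densities (499 cells/mm² at 43 µm mean; 309 at 53 µm) disk
coverage is ≈ 0.70–0.75 — far above the ≈ 0.55 jamming limit of random
sequential ("dart-throwing") placement, so scenes are instead built on a
jittered hexagonal lattice at the exact target count (2 % site surplus,
subsampled), with lognormal diameters (σ_log = 0.18, truncated to
15–100 µm) resolved into a strictly non-overlapping packing by ≤ 60
relaxation iterations (push overlapping neighbors apart, re-grow radii
toward their drawn values Gauss–Seidel-style, final conservative shrink).
σ_log = 0.18 keeps the diameter spread realistic while leaving the printed
density/diameter pairs geometrically reachable. The small residual packing
shrink is offset by per-preset `median_scale` constants (1.005/1.006
exemplar, 1.0 cohort) calibrated once against the generator's own truth
tables and frozen. A configured fraction of cells (1 % inflamed, 0.2 %
control — the realistic CLS prevalence of a few per mm²) become dying
adipocytes at half the scene's healthy mean diameter, each enclosed by a
5 µm protein-rich ring in the space the shrinking cell vacated.

### Rendering and noise

Per pixel, material area fractions are computed at 4×4 supersampling
(partial-volume edges); the transient is `A(x, λ)·s(t) + DC + ε` with a
unit peak-to-peak derivative-of-Gaussian pulse (width 10 samples, centered
at sample 280, support verified to lie inside the energy window) and white
noise. The noise scale is calibrated analytically: the expected range of
n i.i.d. standard normals, `E[range] = ∫ 1 − Φⁿ − (1−Φ)ⁿ dx` (≈ 5.936 for
n = 400), fixes σ so that blocked-beam transients have mean peak-to-peak
1.3 mV at the 50-pulse reference averaging, scaling as 1/√n_averages.

### Spectral cohorts

Cohorts default to the study design: 9 inflamed and 8 control mice with
120/137 spectra each (≈ 2180 total). A cell's spectrum is the squared
lipid absorption (the noise-free signal-energy shape) times
`exp(g_mouse + e_cell) ×` a scalar power jitter (σ = 0.3 log-units) that
the L1 normalization cancels. `g_mouse` and the smooth part of `e_cell`
are Gaussian fields over wavenumber with a squared-exponential kernel
(σ_mouse = 0.10, σ_cell = 0.05, plus a 0.01 white floor).

The kernel length scale (48 cm⁻¹) is the one genuinely coupled design
constant: the Bonferroni family size is estimated as the PCA component
count of 17 psaTS rows, which cannot exceed 16, so the error-rate control
of the method is only self-consistent when the tissue field's effective
dimension is within what 17 subjects can expose. At 24 cm⁻¹ the field has
~40 effective dimensions and the measured family-wise error rate under the
null is ≈ 0.14; at 48 cm⁻¹ the estimator (n_c ≈ 11–14) matches the field
and the measured rate is ≈ 0.055–0.065 over 200 null cohorts (the
acceptance suite recomputes this). Broad-band tissue-level variation is
also the physically plausible regime for composition and coupling effects.

Group effects add `effect_size × √(σ_mouse² + σ_cell² + σ_white²)`
log-units to inflamed mice at the configured wavenumbers — i.e. an effect
expressed in pooled within-group standardized units.

## Morphometry

The segmentation procedure is deterministic and fully parameterized
(`SegmentationParams`): Gaussian smoothing (σ = 1 px) → global Otsu
threshold → hole filling → Euclidean distance transform → seeded watershed
(peaks ≥ 3 px apart) → discard border-touching objects and equivalent
diameters outside 15–100 µm. Two refinements to the textbook recipe,
both forced by dense tissue:

* **Small-hole filling only** (default ≤ 4 px). Filling *every* hole
  absorbs the interstitial matrix of a close-packed field into the
  foreground and erases the per-cell distance maxima (object counts drop
  about three-fold on jammed phantoms); genuine intra-cell holes from
  noise are only ever a few pixels.
* **Analytic boundary debias.** Thresholding the *squared* map at Otsu
  level τ places the object boundary where pixel coverage is
  `√(τ/v_in)` (v_in the foreground plateau) rather than 0.5, eroding
  every radius by the same sub-pixel amount. Reported diameters add the
  closed-form offset `2·(√(τ/v_in) − 0.5)·step` (≈ +2.7 µm at typical τ).
  The correction has no free parameters and vanishes when a linear map is
  thresholded at half its plateau.

`SizeSummary` reports the literal count density n/area and additionally a
border-corrected density (count over the FOV shrunk by one mean diameter
per side): excluding border-touching objects removes those whose centers
fall within one radius of the edge, so the naive ratio is biased low by
≈ 5 % on a 2×2 mm field; the corrected estimate is the one to compare with
true tissue density. Equivalent-circular diameter (CellProfiler
convention) is used throughout; max-Feret would differ for non-circular
objects but the phantom's objects are disks.

## Spectral pre-processing

Stage tags enforce the order shift-correction → laser-profile correction →
L1 normalization → outlier QC → standardization; stages may be skipped but
never applied out of order. Shift correction interpolates only the
2932–2772 cm⁻¹ band (where the laser's tuning error occurred) onto the
nominal grid, with nearest-value extension at the band ends; the shift is
an input, not estimated. The QC combines a LocalOutlierFactor (k = 20,
contamination 0.1) with a 6-s.d. wavenumber-wise median threshold; the
published knobs are unknown, so the defaults are stated in config and the
retention fraction (≈ 0.90 on default cohorts, bracketing the reported
89.2 %) is always reported. Standardization weights each spectrum by the
inverse count of its mouse and uses the population (divide-by-sum-of-
weights) s.d. convention, recorded in the model so the transform is
exactly invertible.

## Inference

Testing operates on per-subject averaged tissue spectra because the
silhouette of mouse labels on standardized spectra is positive (cells from
one tissue are not independent). Welch t-tests are two-sided;
`effective_dof` runs PCA on the mean-centered (not rescaled — the columns
are already standardized upstream) psaTS matrix with an inclusive ≥ 99 %
threshold; the adjustment is `min(1, p·n_c)`. Ties in the ranked low-p
table break by wavenumber, descending. The UMAP-style 2-D embedding is
produced for visualization only; stochastic embeddings are not a test
surface, the silhouette is.

For the effective-d.o.f. recovery study, the constructed 17-row matrix
uses column-centered, exactly orthogonalized equal-variance coefficients
on 12 orthonormal basis spectra plus 0.5 % residual white variance. With
i.i.d. coefficients the smallest of 12 sample eigenvalues from 16 degrees
of freedom routinely falls below a 1 % variance share and the component
count under-reads; orthogonalization realizes the intended 12 equal
eigenvalues exactly, making the construction test the estimator rather
than Wishart fluctuation.

## Problem sizes

Default phantoms are 2×2 mm (400×400 px) single-wavenumber scans —
large enough that border effects are small and per-scene means are tight
(≈ 1200–2000 cells); recovery studies use 20 seeds per preset. Statistical
calibration uses 200 simulated null cohorts at full cohort size. These
sizes were chosen to make the Monte-Carlo error a small fraction of each
tolerance.

## Known limitations

* Disk-shaped cells and a thresholding segmenter mean the morphometry
  validates the pipeline, not biology; real adipocytes are polygonal and
  the original CellProfiler settings are not public.
* Dying adipocytes sit near the detection threshold by construction
  (0.8× contrast, half diameter); at realistic CLS rates their loss is
  immaterial to the size statistics, but the segmenter should not be
  expected to find them reliably.
* The real-data quantities that depend on the study's raw scans (the
  printed SSIM between channels, the exact retention fraction, Table-level
  adjusted p-values) are not reproducible without those scans; the
  corresponding capabilities are exercised on synthetic data instead.
* Bonferroni with a PCA-estimated family size is approximate control, not
  exact; its measured null behavior under the default generator is part of
  the acceptance suite.
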