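# miropath

Analysis pipeline for **label-free histology of white adipose tissue (WAT)
with mid-infrared optoacoustic microscopy**. A tunable quantum cascade laser
raster-scans unstained tissue at selected vibrational transitions; each
absorbed pulse launches an ultrasound transient, and per-pixel summaries of
those transients become micrographs with chemical contrast: lipids at
2852 cm⁻¹ (CH₂ symmetric stretch), protein at 1550 cm⁻¹ (amide II), and a
CH₂/CH₃-bending channel at 1473 cm⁻¹. From these, the package quantifies
the morphological and spectral hallmarks of WAT inflammation — smaller,
more numerous adipocytes, crown-like structures (macrophage rings around
dying adipocytes), and candidate spectral differences between inflamed and
control tissue — without any staining.

It is written for image-analysis and biomedical-optics researchers who want
a tested, reproducible reference implementation of this processing chain,
together with a calibrated synthetic phantom generator that provides ground
truth where no raw scans are available.

## What it computes

**Micrographs and contrast.** For a transient `OAS(t)` the pixel value is
the peak-to-peak amplitude `ptpOAS`. Display and segmentation use the
field-of-view-normalized squared map

```
NOAS²(x, λ) = ptpOAS(x, λ)² / max_x' ptpOAS(x', λ)²  ∈ [0, 1],
```

and contrast-to-noise ratio is `CNR = (ptpOAS_A − ptpOAS_B) / Noise_ptp`,
with the dark noise of the detection chain (1.3 mV peak-to-peak at 50-pulse
averaging) in the denominator.

**Morphometry.** Adipocytes are segmented on the NOAS² lipid map by a
deterministic procedure (Gaussian smoothing → global Otsu threshold →
small-hole filling → seeded watershed on the distance transform → size and
border filters), keeping equivalent diameters between 15 and 100 µm
(3–20 pixels at the 5 µm raster step). Reported diameters carry an
analytic sub-pixel boundary correction (see `docs/methods.md`).

**Spectra.** Per-adipocyte signal-energy spectra
`Spec_SE(λ) = Σ_{i=176}^{400} [OAS(t_i) − S_DC]²` (DC offset from the first
176 samples) are shift-corrected in the C–H band, divided by a carbon-tape
laser reference, L1-normalized to unit total spectral energy, cleaned with
a LocalOutlierFactor + wavenumber-threshold QC, and standardized per
wavenumber with per-mouse inverse-count weights.

**Inference.** Spectra cluster strongly by mouse (positive silhouette), so
testing uses per-subject averaged tissue spectra (psaTS): a two-sided Welch
t-test per wavenumber, with a Bonferroni family size equal to the
*effective degrees of freedom* `n_c` — the number of principal components
of the psaTS matrix reaching 99 % explained variance.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
phantoms calibrated to the instrument's published contrast figures:

```sh
python analysis/01_simulate_phantoms.py --seed 1
python analysis/03_morphometry.py      --seed 1
python analysis/05_group_inference.py  --seed 1
```

prints (abridged):

```
inflamed: 1996 cells over 2x2 mm, true mean diameter 42.9 um, density 499 /mm^2
...
pooled mean diameter: non-inflamed 53.0 um vs inflamed 44.3 um
pooled count density: inflamed 450 vs non-inflamed 294 per mm^2
...
effective degrees of freedom n_c = 12
any Bonferroni-adjusted p < 0.05: False
```

Reading: the inflamed phantom is built with the measured tissue geometry
(smaller cells at higher density); segmentation recovers both group means
to within ~1 µm and the density ordering. On the null spectral cohort (no
injected group effect) the Welch/`n_c` chain declares nothing significant,
as it should. Rerun `05` with `--effect-size 3` to watch the injected
wavenumbers take over the ranked table. A single CNR check,
`(460 − 12)/1.3`, prints the familiar `344:1` lipid contrast
(`miropath cnr`, or `imaging.cnr_from_values` in code).

The same steps are available as a CLI (`miropath simulate|image|cnr|
segment|spectra|test|run`); `miropath run` executes the full chain into a
run directory with a resolved config, per-stage seeds and an output-hash
log.

## Layout

```
src/miropath/        library: grid/containers/io, phantom/, imaging,
                     morphometry, spectral, inference, cli
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md      model, calibration and design notes
```
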