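#!/usr/bin/env python
"""Micrograph formation and contrast metrics on a phantom scene.

Renders the lipid (2852 cm^-1), amide II (1550 cm^-1) and CH2/CH3-bending
(1473 cm^-1) channels of a small inflamed scene, reports per-channel CNR
against the matrix background, the crown-like-ring amide excess, and the
structural similarity between the 2852 and 1473 channels.  Writes
results/contrast.csv and the three NOAS^2 maps as 16-bit TIFFs.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from miropath import GROUP_INFLAMED, WavenumberGrid, imaging
from miropath.constants import DARK_NOISE_PTP_MV
from miropath.io import export_micrograph_tiff
from miropath.phantom import CohortConfig, default_library, render_scan, sample_scene
from miropath.phantom.scene import EXEMPLAR_PRESETS

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

preset = dataclasses.replace(EXEMPLAR_PRESETS[GROUP_INFLAMED], fov_um=1000.0, cls_rate=0.02)
cfg = CohortConfig(scene_presets={GROUP_INFLAMED: preset})
scene = sample_scene(cfg, GROUP_INFLAMED, seed=args.seed)
lib = default_library()
grid = WavenumberGrid(np.array([2852.55, 1550.55, 1473.55]))
cube = render_scan(scene, lib, grid, seed=args.seed + 1, dtype=np.float32)

# pixel picks from the ground-truth table: a healthy cell center and matrix
cells = scene.cells()
healthy = cells[cells["type"] == "adipocyte"].iloc[0]
cell_px = (int(healthy.y_um / 5), int(healthy.x_um / 5))
# matrix pixel: farthest label-map zero pixel from any object
from scipy import ndimage as ndi

ecm_dist = ndi.distance_transform_edt(scene.label_map == 0)
ecm_px = np.unravel_index(np.argmax(ecm_dist), ecm_dist.shape)

rows = []
for w in grid.values:
    m = imaging.build_micrograph(cube, w)
    report = imaging.cnr(m, cell_px, tuple(ecm_px), DARK_NOISE_PTP_MV)
    rows.append(
        dict(
            wavenumber_cm1=w,
            ptp_cell_mv=report.ptp_a_mv,
            ptp_matrix_mv=report.ptp_b_mv,
            cnr=report.cnr,
            cnr_integer=report.cnr_integer,
        )
    )
    export_micrograph_tiff(
        imaging.normalize_noas2(m), args.out / f"map_{w:.0f}.tif"
    )

df = pd.DataFrame(rows)
df.to_csv(args.out / "contrast.csv", index=False)
print(df.to_string(index=False))

m2852 = imaging.normalize_noas2(imaging.build_micrograph(cube, 2852.55))
m1473 = imaging.normalize_noas2(imaging.build_micrograph(cube, 1473.55))
ssim = imaging.ssim_index(m2852, m1473)
print(f"SSIM(2852, 1473) = {ssim:.2f}  (same cells, different band weights)")

ring_ecm = lib.evaluate("cls_ring", WavenumberGrid.single(1550.0))[0] / lib.evaluate(
    "protein_ecm", WavenumberGrid.single(1550.0)
)[0]
print(f"crown-like ring amide II excess over matrix: {ring_ecm:.2f}x")
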