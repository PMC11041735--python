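import numpy as np
import pandas as pd
import pytest

from miropath import GROUP_INFLAMED, GROUP_NON_INFLAMED, WavenumberGrid, imaging, morphometry
from miropath.phantom import CohortConfig, default_library, render_scan, sample_scene
from miropath.phantom.scene import PhantomScene, rasterize_labels

LIPID = 2852.55


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig()


def make_scene_from_objects(objects: pd.DataFrame, fov_um: float, group=GROUP_NON_INFLAMED):
    """Hand-built scene for unit tests (bypasses the packing generator)."""
    label = rasterize_labels(objects, fov_um, 5.0)
    return PhantomScene(label, objects, fov_um, 5.0, "fixture", group)


@pytest.fixture(scope="session")
def exemplar_segmentation(library, cohort_config):
    """One rendered + segmented exemplar scene per group (shared, seeded)."""
    out = {}
    for i, group in enumerate((GROUP_NON_INFLAMED, GROUP_INFLAMED)):
        scene = sample_scene(cohort_config, group, seed=40 + i)
        cube = render_scan(
            scene,
            library,
            WavenumberGrid.single(LIPID),
            seed=140 + i,
            dtype=np.float32,
        )
        noas2 = imaging.normalize_noas2(imaging.build_micrograph(cube, LIPID))
        labels, cells = morphometry.segment_adipocytes(noas2)
        fov_mm2 = (scene.fov_um / 1000.0) ** 2
        out[group] = dict(
            scene=scene,
            noas2=noas2,
            cells=cells,
            summary=morphometry.summarize_sizes(cells, fov_mm2),
        )
    return out
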