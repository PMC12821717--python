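import numpy as np
import pytest

from sox10md.core import BasalContour, NucleusInstance, cumulative_arc_mm
from sox10md.synth import SceneSpec, generate_scene

# tile parameters small enough for fast tests but tall enough to hold the
# epidermis band plus dermis at 1 µm/px
SMALL_TILE = dict(
    tile_size_px=(192, 512),
    microns_per_pixel=1.0,
    epidermis_thickness_um=40.0,
    epidermis_waviness_um=8.0,
    surface_margin_um=20.0,
)


def small_spec(**kw) -> SceneSpec:
    merged = {**SMALL_TILE, **kw}
    return SceneSpec(**merged)


@pytest.fixture(scope="session")
def default_scene():
    spec = SceneSpec(seed=7, junctional_density_per_mm=40, nest_count=2,
                     dermal_distractor_density_per_mm2=10)
    return spec, *generate_scene(spec)


@pytest.fixture(scope="session")
def isolated_scene():
    """Scene with background nuclei kept isolated, so generated nests are
    the only confluent clusters."""
    spec = SceneSpec(seed=11, junctional_density_per_mm=25, nest_count=2,
                     min_nucleus_spacing_um=12.0)
    return spec, *generate_scene(spec)


@pytest.fixture(scope="session")
def training_set():
    """Eight small tiles with masks for toy segmenter training."""
    images, gts = [], []
    for seed in range(8):
        spec = small_spec(tile_size_px=(128, 128), seed=seed, junctional_density_per_mm=30)
        img, gt = generate_scene(spec)
        images.append(img)
        gts.append(gt)
    return images, gts


@pytest.fixture(scope="session")
def trained_segmenters(training_set):
    from sox10md.epidermis import train_epidermis_segmenter
    from sox10md.nuclei import centroid_disk_masks, train_nuclei_segmenter
    from sox10md.segmenter import SegmenterConfig

    images, gts = training_set
    emasks = [gt.epidermis_mask for gt in gts]
    nmasks = []
    for img, gt in zip(images, gts):
        xy = np.concatenate([gt.junctional_xy, gt.dermal_xy]) if len(gt.dermal_xy) else gt.junctional_xy
        nmasks.append(centroid_disk_masks(img.shape, xy, 3.0, img.microns_per_pixel))
    cfg = SegmenterConfig(epochs=5, seed=1, patch_size_px=128)
    return (
        train_epidermis_segmenter(images, emasks, cfg),
        train_nuclei_segmenter(images, nmasks, cfg),
    )


def straight_contour(length_mm: float, mpp: float = 1.0, y: float = 50.0) -> BasalContour:
    """Horizontal synthetic basal border of exactly `length_mm`."""
    n = int(round(length_mm * 1000.0 / mpp)) + 1
    points = np.stack([np.arange(n, dtype=float), np.full(n, y)], axis=1)
    arc = cumulative_arc_mm(points, mpp)
    normals = np.tile([0.0, 1.0], (n, 1))
    return BasalContour(points, arc, mpp, segment_id=0, normals=normals)


def junctional_instance(arc_mm: float, inst_id: int = 0) -> NucleusInstance:
    return NucleusInstance(
        id=inst_id, centroid=(arc_mm * 1000.0, 50.0), area_um2=28.0,
        arc_mm=arc_mm, depth_um=0.0, contour_id=0, junctional=True,
    )
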