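"""Nuclear signal detection, instance separation, and junctional filtering.

Candidate nuclear regions come from thresholding a per-pixel probability
map at 0.5. Touching nuclei are split by marker-controlled watershed:
local maxima of the Gaussian-smoothed probability map seed a watershed on
the inverted Euclidean distance transform of the binary mask, restricted
to the mask. Instances below a minimum area are dropped as specks.

Only nuclei whose centroid lies within the configured band (default
10 µm) of the basal epidermal border count as junctional melanocytes; all
others are kept for audit but excluded from density computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import BasalContour, CalibratedImage, NucleusInstance, ProbabilityMap
from .errors import ConfigurationError, FilterError
from .segmenter import SegmenterConfig, TrainResult, train_segmenter


@dataclass
class InstanceSeparationConfig:
    """Watershed post-processing parameters (physical units)."""

    binarisation_threshold: float = 0.5
    smoothing_sigma_um: float = 1.0
    min_seed_distance_um: float = 3.0
    min_instance_area_um2: float = 8.0
    magnification_level: str = "20x"

    def __post_init__(self) -> None:
        if not 0 < self.binarisation_threshold < 1:
            raise ConfigurationError("binarisation_threshold must lie in (0, 1)")
        if self.min_seed_distance_um <= 0:
            raise ConfigurationError("min_seed_distance_um must be positive")
        if self.smoothing_sigma_um < 0:
            raise ConfigurationError("smoothing_sigma_um must be non-negative")
        if self.min_instance_area_um2 <= 0:
            raise ConfigurationError("min_instance_area_um2 must be positive")


@dataclass
class JunctionalFilterConfig:
    """Band around the basal border that defines 'junctional'."""

    band_um: float = 10.0
    side: str = "symmetric"  # symmetric | epidermal_only | dermal_only

    def __post_init__(self) -> None:
        if self.band_um <= 0:
            raise ConfigurationError("band_um must be positive")
        if self.side not in ("symmetric", "epidermal_only", "dermal_only"):
            raise ConfigurationError(f"unknown side {self.side!r}")


def train_nuclei_segmenter(
    images: list[CalibratedImage], masks: list[np.ndarray], config: SegmenterConfig
) -> TrainResult:
    """Train the nuclear-signal pixel segmenter (validation pixel F1)."""
    return train_segmenter(images, masks, config, kind="nuclei", metric="f1")


def centroid_disk_masks(
    shape: tuple[int, int], centroids: np.ndarray, radius_um: float, mpp: float
) -> np.ndarray:
    """Training mask of fixed-radius disks centred on annotated nuclei."""
    out = np.zeros(shape, dtype=bool)
    r = radius_um / mpp
    h, w = shape
    for cx, cy in centroids:
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    return out


# ---------------------------------------------------------------------------
# instance separation
# ---------------------------------------------------------------------------

def separate_instances(
    prob_map: ProbabilityMap, config: InstanceSeparationConfig | None = None
) -> tuple[list[NucleusInstance], np.ndarray]:
    """Split the thresholded probability map into nucleus instances.

    Pipeline order is fixed: binarise -> smooth probability map -> local
    maxima (seeds) -> watershed on the inverted distance transform of the
    binary mask -> drop instances below the minimum area. The returned
    label image partitions the binary mask minus dropped specks; the
    instance list carries centroids and areas in physical units.
    """
    config = config or InstanceSeparationConfig()
    mpp = prob_map.microns_per_pixel
    binary = prob_map.values >= config.binarisation_threshold
    if not binary.any():
        return [], np.zeros(prob_map.shape, dtype=np.int32)

    sigma_px = config.smoothing_sigma_um / mpp
    smoothed = ndi.gaussian_filter(prob_map.values, sigma_px) if sigma_px > 0 else prob_map.values
    min_dist_px = max(int(round(config.min_seed_distance_um / mpp)), 1)
    peaks = peak_local_max(
        smoothed, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(prob_map.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if len(peaks) == 0:  # degenerate: mask without a probability peak
        markers, _ = ndi.label(binary)

    distance = ndi.distance_transform_edt(binary)
    labels = watershed(-distance, markers, mask=binary)

    # a blob whose only peak was suppressed by a stronger neighbour (global
    # min-distance) has no marker; adopt such marker-less regions whole so
    # the labels still partition the mask
    leftover = binary & (labels == 0)
    if leftover.any():
        extra, _n = ndi.label(leftover)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0).astype(labels.dtype)

    min_area_px = config.min_instance_area_um2 / (mpp * mpp)
    instances: list[NucleusInstance] = []
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        out[labels == rp.label] = next_id
        instances.append(
            NucleusInstance(
                id=next_id,
                centroid=(float(cx), float(cy)),
                area_um2=float(rp.area) * mpp * mpp,
                label=next_id,
            )
        )
        next_id += 1
    return instances, out


def instances_from_labels(labels: np.ndarray, mpp: float) -> tuple[list[NucleusInstance], np.ndarray]:
    """Adopt a ground-truth label image directly as nucleus instances (oracle backend)."""
    instances = []
    for rp in regionprops(labels.astype(np.int32)):
        cy, cx = rp.centroid
        instances.append(
            NucleusInstance(
                id=int(rp.label),
                centroid=(float(cx), float(cy)),
                area_um2=float(rp.area) * mpp * mpp,
                label=int(rp.label),
            )
        )
    return instances, labels.astype(np.int32)


def filter_stain_hue(
    instances: list[NucleusInstance],
    image: CalibratedImage,
    labels: np.ndarray,
    hue_interval: tuple[float, float] = (0.0, 0.16),
) -> list[NucleusInstance]:
    """Optional artefact pre-filter: drop detections whose mean hue falls
    outside the chromogen's hue interval (brown ~ 0.02-0.1).

    Rejects colour-marker ink and dirt, which detect as dark blobs but are
    typically blue/green. Off by default in the pipeline.
    """
    hsv = rgb2hsv(image.pixels)
    lo, hi = hue_interval
    kept = []
    for inst in instances:
        sel = labels == inst.label
        if not sel.any():
            continue
        h = float(hsv[..., 0][sel].mean())
        if lo <= h <= hi:
            kept.append(inst)
    return kept


# ---------------------------------------------------------------------------
# junctional filter
# ---------------------------------------------------------------------------

def filter_junctional(
    instances: list[NucleusInstance],
    contours: list[BasalContour],
    config: JunctionalFilterConfig | None = None,
) -> list[NucleusInstance]:
    """Annotate instances with depth/arc position and flag junctional ones.

    Every instance is assigned its nearest basal-contour point over all
    contours; ``depth_um`` is signed positive into the dermis. Instances
    with |depth| <= band (or the one-sided variant) are marked junctional.
    All instances are returned (the excluded ones for audit); the
    operation is idempotent.
    """
    config = config or JunctionalFilterConfig()
    if not contours:
        raise FilterError("no basal contours: cannot assign arc positions")
    trees = [cKDTree(c.points) for c in contours]
    for inst in instances:
        best = None
        for cid, (c, tree) in enumerate(zip(contours, trees)):
            d, idx = tree.query(inst.centroid)
            if best is None or d < best[0]:
                best = (d, idx, cid)
        d_px, idx, cid = best
        c = contours[cid]
        mpp = c.microns_per_pixel
        vec = np.asarray(inst.centroid) - c.points[idx]
        normal = c.normals[idx] if c.normals is not None else np.array([0.0, 1.0])
        sign = 1.0 if float(vec @ normal) >= 0 else -1.0
        inst.depth_um = sign * d_px * mpp
        inst.arc_mm = float(c.arc_mm[idx])
        inst.contour_id = cid
        if config.side == "symmetric":
            inst.junctional = abs(inst.depth_um) <= config.band_um
        elif config.side == "epidermal_only":
            inst.junctional = -config.band_um <= inst.depth_um <= 0
        else:  # dermal_only
            inst.junctional = 0 <= inst.depth_um <= config.band_um
    return instances


def junctional_only(instances: list[NucleusInstance]) -> list[NucleusInstance]:
    return [i for i in instances if i.junctional]


def count_reference_window(
    instances: list[NucleusInstance],
    contours: list[BasalContour],
    window_mm: float = 0.5,
    stride_mm: float = 0.1,
) -> int:
    """Count in the most densely affected window — the automated analogue
    of manually counting melanocytes over the densest 0.5 mm span.

    Returns the maximum raw window count over all contours (short contours
    contribute their full-length count without extrapolation here, since a
    manual count is a raw tally).
    """
    from .density import compute_density_profile, CutoffScheme

    best = 0
    scheme = CutoffScheme(window_mm=window_mm)
    for c in contours:
        inst = [i for i in junctional_only(instances) if i.contour_id == c.segment_id]
        windows = compute_density_profile(inst, c, scheme, stride_mm=stride_mm)
        for wdw in windows:
            best = max(best, wdw.count)
    return best
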