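"""Epidermis segmentation and basal-border extraction.

The epidermis detector classifies epidermis plus adnexal epithelium
against background on 512 px tiles, thresholds the probability map at 0.5
(probability >= threshold counts as epidermis), cleans the binary mask,
and extracts the *basal* border of every epidermal fragment as an
arc-length-parameterised polyline. Density windows and the junctional
filter all measure along that polyline.

The basal side is identified as the mask boundary adjacent to tissue
(dermis) rather than to the bright slide background; when no tissue mask
is available an explicit orientation hint resolves the ambiguity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter1d

from .core import BasalContour, CalibratedImage, ProbabilityMap, cumulative_arc_mm
from .errors import ConfigurationError, OrientationError
from .segmenter import PixelSegmenter, SegmenterConfig, TrainResult, train_segmenter

_HINTS = {"surface=top": (1, 0), "surface=bottom": (-1, 0),
          "surface=left": (0, 1), "surface=right": (0, -1)}
# hint -> (dy, dx) unit step pointing from epidermis toward the dermis


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_image(image: CalibratedImage, patch_size: int = 512, overlap_px: int = 0):
    """Tile an image into ``patch_size`` squares covering every pixel.

    Images smaller than one patch are zero-padded. The last row/column of
    patches is shifted inward so patches never leave the (padded) raster;
    with ``overlap_px`` > 0 interior patches overlap by at least that much.

    Returns ``(patches, offsets, padded_shape)`` where ``offsets`` are
    ``(y, x)`` of each patch's top-left corner in the padded raster.
    """
    if overlap_px < 0 or overlap_px >= patch_size:
        raise ConfigurationError("overlap_px must satisfy 0 <= overlap < patch_size")
    h, w = image.shape
    ph, pw = max(h, patch_size), max(w, patch_size)
    padded = image.pixels
    if (ph, pw) != (h, w):
        padded = np.zeros((ph, pw, 3), dtype=image.pixels.dtype)
        padded[:h, :w] = image.pixels

    stride = patch_size - overlap_px

    def starts(extent: int) -> list[int]:
        s = list(range(0, max(extent - patch_size, 0) + 1, stride))
        if s[-1] + patch_size < extent:
            s.append(extent - patch_size)
        return s

    patches, offsets = [], []
    for y0 in starts(ph):
        for x0 in starts(pw):
            patches.append(padded[y0:y0 + patch_size, x0:x0 + patch_size])
            offsets.append((y0, x0))
    return patches, offsets, (ph, pw)


def reassemble(patches, offsets, padded_shape, out_shape=None) -> np.ndarray:
    """Stitch per-patch rasters back together, averaging overlaps."""
    ph, pw = padded_shape
    sample = np.asarray(patches[0], dtype=float)
    extra = sample.shape[2:]
    acc = np.zeros((ph, pw) + extra, dtype=float)
    cnt = np.zeros((ph, pw) + (1,) * len(extra), dtype=float)
    for patch, (y0, x0) in zip(patches, offsets):
        p = np.asarray(patch, dtype=float)
        s = p.shape[:2]
        acc[y0:y0 + s[0], x0:x0 + s[1]] += p
        cnt[y0:y0 + s[0], x0:x0 + s[1]] += 1
    out = acc / np.maximum(cnt, 1)
    if out_shape is not None:
        out = out[: out_shape[0], : out_shape[1]]
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def train_epidermis_segmenter(
    images: list[CalibratedImage], masks: list[np.ndarray], config: SegmenterConfig
) -> TrainResult:
    """Train the epidermis-vs-background pixel segmenter (validation IoU)."""
    return train_segmenter(images, masks, config, kind="epidermis", metric="iou")


def segment_epidermis(
    image: CalibratedImage,
    segmenter: PixelSegmenter | None = None,
    threshold: float = 0.5,
    oracle_mask: np.ndarray | None = None,
    probability_map: ProbabilityMap | None = None,
) -> np.ndarray:
    """Binary epidermis mask from a segmenter, a probability map, or an oracle.

    The tie rule is fixed: probability >= threshold maps to epidermis.
    With ``oracle_mask`` the ground-truth mask is returned unchanged.
    """
    if oracle_mask is not None:
        return np.asarray(oracle_mask).astype(bool)
    if probability_map is not None:
        return probability_map.values >= threshold
    if segmenter is None:
        raise ConfigurationError("need a segmenter, probability map, or oracle mask")
    if image.microns_per_pixel <= 0:
        raise ConfigurationError("calibration missing")
    return segmenter.predict_probability(image).values >= threshold


def tissue_from_image(image: CalibratedImage, brightness_threshold: float = 240.0) -> np.ndarray:
    """Rough tissue mask: anything darker than the blank slide background."""
    mean = image.pixels.astype(float).mean(axis=2)
    tissue = mean < brightness_threshold
    tissue = ndi.binary_opening(tissue, structure=np.ones((3, 3)))
    tissue = ndi.binary_closing(tissue, structure=np.ones((3, 3)))
    return tissue


# ---------------------------------------------------------------------------
# basal contour extraction
# ---------------------------------------------------------------------------

def _clean_mask(mask: np.ndarray, mpp: float, min_object_um2: float = 50.0) -> np.ndarray:
    """Fill pinholes and drop sub-nuclear specks before contour tracing."""
    mask = ndi.binary_fill_holes(mask.astype(bool))
    min_px = max(int(round(min_object_um2 / (mpp * mpp))), 1)
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(lab, keep)


def _basal_direction(mask: np.ndarray, boundary: np.ndarray, tissue: np.ndarray | None,
                     hint: str | None) -> tuple[float, float]:
    """Mean (dy, dx) from boundary pixels toward adjacent dermis."""
    if hint is not None:
        if hint not in _HINTS:
            raise OrientationError(f"unknown orientation hint {hint!r}")
        return _HINTS[hint]
    if tissue is None:
        raise OrientationError("no tissue mask and no orientation hint")
    votes = np.zeros(2)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    outside_tissue = tissue & ~mask
    ys, xs = np.nonzero(boundary)
    h, w = mask.shape
    for dy, dx in offsets:
        ny, nx = ys + dy, xs + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        hits = outside_tissue[ny[ok], nx[ok]]
        votes += hits.sum() * np.array([dy, dx]) / np.hypot(dy, dx)
    norm = np.hypot(*votes)
    if norm == 0:
        raise OrientationError("boundary touches no tissue; cannot find basal side")
    return tuple(votes / norm)


def _trace_basal(frag: np.ndarray, direction: tuple[float, float]) -> np.ndarray:
    """Basal polyline of one fragment as (x, y) float points.

    The fragment is scanned along the axis perpendicular to the basal
    direction; for each scan position the extreme mask pixel toward the
    dermis is taken, and the resulting integer profile is smoothed to
    undo pixel quantisation (which would otherwise inflate arc length).
    """
    dy, dx = direction
    along_x = abs(dy) >= abs(dx)  # dermis above/below -> border runs along x
    if along_x:
        cols = np.flatnonzero(frag.any(axis=0))
        ys = np.where(dy > 0,
                      frag.shape[0] - 1 - np.argmax(frag[::-1, :], axis=0),
                      np.argmax(frag, axis=0))
        prof = ys[cols].astype(float)
        if len(cols) >= 5:
            prof = gaussian_filter1d(prof, sigma=2.0, mode="nearest")
        return np.stack([cols.astype(float), prof], axis=1)
    rows = np.flatnonzero(frag.any(axis=1))
    xs = np.where(dx > 0,
                  frag.shape[1] - 1 - np.argmax(frag[:, ::-1], axis=1),
                  np.argmax(frag, axis=1))
    prof = xs[rows].astype(float)
    if len(rows) >= 5:
        prof = gaussian_filter1d(prof, sigma=2.0, mode="nearest")
    return np.stack([prof, rows.astype(float)], axis=1)


def contours_to_geojson(contours: list[BasalContour]) -> dict:
    """Basal contours as a GeoJSON FeatureCollection of LineStrings in
    pixel coordinates, calibration and arc length in the properties."""
    features = []
    for c in contours:
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in c.points],
            },
            "properties": {
                "segment_id": c.segment_id,
                "microns_per_pixel": c.microns_per_pixel,
                "length_mm": c.length_mm,
                "adnexal": c.adnexal,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def extract_basal_contour(
    mask: np.ndarray,
    microns_per_pixel: float,
    tissue_mask: np.ndarray | None = None,
    orientation_hint: str | None = None,
    min_fragment_um: float = 100.0,
) -> list[BasalContour]:
    """Extract the basal border of each epidermal fragment.

    Fragments whose basal border is shorter than ``min_fragment_um`` are
    discarded as speck noise. An empty mask yields an empty list. Without
    a tissue mask the ``orientation_hint`` (``"surface=top"`` etc.) names
    which side of the band is the skin surface.
    """
    mask = _clean_mask(np.asarray(mask).astype(bool), microns_per_pixel)
    if not mask.any():
        return []
    lab, n = ndi.label(mask)
    contours: list[BasalContour] = []
    seg_id = 0
    for i in range(1, n + 1):
        frag = lab == i
        boundary = frag & ~ndi.binary_erosion(frag, border_value=0)
        try:
            direction = _basal_direction(frag, boundary, tissue_mask, orientation_hint)
        except OrientationError:
            if tissue_mask is None and orientation_hint is None:
                raise
            continue  # fragment with no resolvable basal side (e.g. island in background)
        points = _trace_basal(frag, direction)
        arc = cumulative_arc_mm(points, microns_per_pixel)
        if len(points) < 2 or arc[-1] * 1000.0 < min_fragment_um:
            continue
        tangents = np.gradient(points, axis=0)
        tnorm = np.linalg.norm(tangents, axis=1, keepdims=True)
        tangents = tangents / np.maximum(tnorm, 1e-12)
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        want = np.array([direction[1], direction[0]])  # (dx, dy) toward dermis
        flip = normals @ want < 0
        normals[flip] *= -1
        contours.append(
            BasalContour(points, arc, microns_per_pixel, segment_id=seg_id, normals=normals)
        )
        seg_id += 1
    return contours
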