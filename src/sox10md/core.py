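"""Core calibrated-raster containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class CalibratedImage:
    """An RGB raster together with its physical pixel size.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    microns_per_pixel
        Physical edge length of one pixel in micrometres. All downstream
        distances (the 10 µm junctional band, 0.5 mm density windows) are
        expressed in physical units and converted through this factor.
    name
        Optional slide / tile identifier carried into reports.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.microns_per_pixel is None or self.microns_per_pixel <= 0:
            raise ConfigurationError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigurationError("image must be an (H, W, 3) RGB raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def px_per_mm(self) -> float:
        return 1000.0 / self.microns_per_pixel


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probability in ``[0, 1]`` with calibration."""

    values: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.microns_per_pixel <= 0:
            raise ConfigurationError("microns_per_pixel must be positive")
        lo, hi = float(self.values.min(initial=0.0)), float(self.values.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ConfigurationError(f"probabilities outside [0, 1]: [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BasalContour:
    """The lower (basal) epidermal border of one epidermal fragment.

    The polyline is parameterised by cumulative arc length so that nuclei
    can be located along the junction and counted in 0.5 mm windows.

    Attributes
    ----------
    points
        ``(N, 2)`` array of ``(x, y)`` pixel coordinates ordered along the
        border.
    arc_mm
        ``(N,)`` cumulative arc length per vertex, in millimetres, starting
        at 0 for the first vertex.
    normals
        ``(N, 2)`` unit vectors perpendicular to the border, oriented from
        the epidermis into the dermis. Used for the sign of nucleus depth.
    microns_per_pixel
        Calibration of the source raster.
    segment_id
        Index of the epidermal fragment this border belongs to.
    adnexal
        True when the fragment was flagged as adnexal epithelium (follicle
        wall) rather than surface epidermis.
    """

    points: np.ndarray
    arc_mm: np.ndarray
    microns_per_pixel: float
    segment_id: int = 0
    normals: np.ndarray | None = None
    adnexal: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_mm = np.asarray(self.arc_mm, dtype=float)
        if len(self.points) != len(self.arc_mm):
            raise ConfigurationError("points and arc_mm length mismatch")
        if len(self.arc_mm) and np.any(np.diff(self.arc_mm) < -1e-12):
            raise ConfigurationError("arc length must be non-decreasing")

    @property
    def length_mm(self) -> float:
        return float(self.arc_mm[-1]) if len(self.arc_mm) else 0.0


def polyline_length_mm(points: np.ndarray, microns_per_pixel: float) -> float:
    """Arc length of a pixel-coordinate polyline, in millimetres."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return float(seg.sum() * microns_per_pixel / 1000.0)


def cumulative_arc_mm(points: np.ndarray, microns_per_pixel: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.zeros(0)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)]) * microns_per_pixel / 1000.0


@dataclass
class NucleusInstance:
    """One separated nuclear immunostain signal.

    ``depth_um`` is the perpendicular distance from the centroid to the
    nearest basal-contour point, signed positive into the dermis and
    negative into the epidermis. ``arc_mm`` is the arc-length position of
    that nearest contour point; both are filled by the junctional filter.
    """

    id: int
    centroid: tuple[float, float]  # (x, y) px
    area_um2: float
    label: int = 0  # value in the instance label image
    depth_um: float = float("nan")
    arc_mm: float = float("nan")
    contour_id: int = -1
    junctional: bool = False
    nest_id: int = -1

    def as_row(self) -> dict:
        return {
            "id": self.id,
            "x_px": self.centroid[0],
            "y_px": self.centroid[1],
            "area_um2": self.area_um2,
            "depth_um": self.depth_um,
            "arc_mm": self.arc_mm,
            "contour_id": self.contour_id,
            "junctional": self.junctional,
            "nest_id": self.nest_id,
        }
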