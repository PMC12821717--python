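"""Melanocyte-density profiling, traffic-light classification, slide calls,
and heat-map rendering.

The central statistic is the melanocyte density (MD): the number of
junctional melanocytes per 0.5 mm of basal epidermal length. Windows of
``window_mm`` slide along each basal contour at ``stride_mm``; counts in
short (partial or sub-window) segments are rescaled to a per-0.5 mm
density and flagged as extrapolated. Window densities map to three zones:

* red    — density >= 30 per 0.5 mm (affected),
* yellow — 25 <= density < 30 (borderline),
* green  — density < 25 (negative).

A slide's call is driven by its most densely affected window (maximum
window density), mirroring how the densest area is selected for a manual
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk

from .core import BasalContour, CalibratedImage, NucleusInstance
from .errors import ConfigurationError

ZONES = ("green", "yellow", "red")
_SEVERITY = {"green": 0, "yellow": 1, "red": 2}
DEFAULT_COLORS = {"green": (46, 160, 67), "yellow": (227, 179, 65), "red": (207, 34, 46)}
MIN_EVALUABLE_MM = 0.1  # shorter windows are reported but flagged insufficient


@dataclass
class CutoffScheme:
    """Density cutoffs for the three-colour scheme (all customisable)."""

    red_min: float = 30.0
    yellow_min: float = 25.0
    window_mm: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.yellow_min <= self.red_min:
            raise ConfigurationError(
                f"need 0 < yellow_min <= red_min, got {self.yellow_min}, {self.red_min}"
            )
        if self.window_mm <= 0:
            raise ConfigurationError("window_mm must be positive")


@dataclass
class DensityWindow:
    """One arc-length window on one basal contour."""

    contour_id: int
    start_mm: float
    end_mm: float
    count: int
    density_per_half_mm: float
    zone: str
    extrapolated: bool = False
    insufficient: bool = False

    def as_row(self) -> dict:
        return {
            "contour_id": self.contour_id,
            "start_mm": self.start_mm,
            "end_mm": self.end_mm,
            "count": self.count,
            "density_per_half_mm": self.density_per_half_mm,
            "zone": self.zone,
            "extrapolated": self.extrapolated,
            "insufficient": self.insufficient,
        }


@dataclass
class SlideReport:
    """Slide-level outcome assembled from all contours."""

    slide_id: str
    windows: list[DensityWindow] = field(default_factory=list)
    max_density: float = 0.0
    slide_call: str = "negative"  # positive | borderline | negative | indeterminate
    nest_flag: bool = False
    n_instances: int = 0
    n_junctional: int = 0
    n_excluded: int = 0
    n_contours: int = 0
    status: str = "ok"
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "status": self.status,
            "max_density": self.max_density,
            "slide_call": self.slide_call,
            "nest_flag": self.nest_flag,
            "n_instances": self.n_instances,
            "n_junctional": self.n_junctional,
            "n_excluded": self.n_excluded,
            "n_contours": self.n_contours,
            "windows": [w.as_row() for w in self.windows],
            "config": self.config_echo,
        }


def classify_window(density: float, scheme: CutoffScheme | None = None) -> str:
    """Map a per-0.5 mm density to its traffic-light zone.

    Boundaries are closed on the stated side: exactly ``red_min`` is red,
    exactly ``yellow_min`` is yellow.
    """
    scheme = scheme or CutoffScheme()
    if density >= scheme.red_min:
        return "red"
    if density >= scheme.yellow_min:
        return "yellow"
    return "green"


def compute_density_profile(
    instances: list[NucleusInstance],
    contour: BasalContour,
    scheme: CutoffScheme | None = None,
    stride_mm: float = 0.1,
) -> list[DensityWindow]:
    """Sliding-window junctional counts along one basal contour.

    Windows start at 0, stride_mm, 2*stride_mm, ... while the start lies on
    the contour; a window reaching past the end (or a contour shorter than
    one window) is truncated and its count linearly rescaled to a
    per-``window_mm`` density with ``extrapolated=True``. Truncated windows
    shorter than 0.1 mm are additionally flagged ``insufficient``.
    """
    scheme = scheme or CutoffScheme()
    if stride_mm <= 0:
        raise ConfigurationError("stride_mm must be positive")
    total = contour.length_mm
    if total <= 0:
        return []
    arcs = np.array([i.arc_mm for i in instances if i.junctional], dtype=float)
    eps = 1e-9
    windows: list[DensityWindow] = []
    start = 0.0
    k = 0
    while start < total - eps or k == 0:
        end = min(start + scheme.window_mm, total)
        actual = end - start
        if actual <= eps:
            break
        count = int(np.sum((arcs >= start - eps) & (arcs < end - eps))) if len(arcs) else 0
        # the contour's last instance sits exactly at arc == total; the final
        # window is closed on the right so it is not lost
        if len(arcs) and end >= total - eps:
            count = int(np.sum((arcs >= start - eps) & (arcs <= end + eps)))
        extrapolated = actual < scheme.window_mm - eps
        density = count * (scheme.window_mm / actual) if extrapolated else float(count)
        windows.append(
            DensityWindow(
                contour_id=contour.segment_id,
                start_mm=round(start, 9),
                end_mm=round(end, 9),
                count=count,
                density_per_half_mm=density,
                zone=classify_window(density, scheme),
                extrapolated=extrapolated,
                insufficient=actual < MIN_EVALUABLE_MM - eps,
            )
        )
        k += 1
        start = k * stride_mm
    return windows


def slide_call(windows: list[DensityWindow], scheme: CutoffScheme | None = None) -> tuple[float, str]:
    """Maximum window density and the derived slide-level call.

    Insufficiently short windows are excluded from the maximum unless no
    other windows exist. Returns ``(max_density, call)`` with the call in
    {positive, borderline, negative, indeterminate}.
    """
    scheme = scheme or CutoffScheme()
    usable = [w for w in windows if not w.insufficient] or list(windows)
    if not usable:
        return 0.0, "indeterminate"
    max_density = max(w.density_per_half_mm for w in usable)
    zone = classify_window(max_density, scheme)
    call = {"red": "positive", "yellow": "borderline", "green": "negative"}[zone]
    return float(max_density), call


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_heatmap(
    image: CalibratedImage,
    contours: list[BasalContour],
    windows: list[DensityWindow],
    stroke_px: int = 3,
    colors: dict | None = None,
    legend: bool = True,
) -> np.ndarray:
    """Paint the basal contour in traffic-light colours over a copy of the image.

    Each contour vertex takes the colour of the highest-severity window
    covering its arc position (red > yellow > green). A small legend and a
    0.5 mm scale bar are drawn in the corners. The input raster is never
    modified.
    """
    colors = colors or DEFAULT_COLORS
    out = image.pixels.copy()
    h, w = out.shape[:2]
    by_contour: dict[int, list[DensityWindow]] = {}
    for win in windows:
        by_contour.setdefault(win.contour_id, []).append(win)
    for c in contours:
        wins = by_contour.get(c.segment_id, [])
        if not wins:
            continue
        starts = np.array([x.start_mm for x in wins])
        ends = np.array([x.end_mm for x in wins])
        sev = np.array([_SEVERITY[x.zone] for x in wins])
        for (x, y), s in zip(c.points, c.arc_mm):
            cover = (starts <= s) & (s <= ends)
            if not cover.any():
                continue
            zone = ZONES[int(sev[cover].max())]
            rr, cc = draw_disk((y, x), stroke_px, shape=(h, w))
            out[rr, cc] = colors[zone]
    if legend and contours:
        _draw_legend(out, colors)
        _draw_scale_bar(out, image.microns_per_pixel)
    return out


def _draw_legend(out: np.ndarray, colors: dict, pad: int = 6, box: int = 10) -> None:
    y = pad
    for zone in ("red", "yellow", "green"):
        x = pad
        y1, x1 = min(y + box, out.shape[0]), min(x + box, out.shape[1])
        out[y:y1, x:x1] = colors[zone]
        y = y1 + 4


def _draw_scale_bar(out: np.ndarray, mpp: float, length_mm: float = 0.5) -> None:
    h, w = out.shape[:2]
    bar_px = int(round(length_mm * 1000.0 / mpp))
    if bar_px + 12 > w:
        return
    y0 = h - 12
    out[y0 : y0 + 4, 6 : 6 + bar_px] = (20, 20, 20)
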