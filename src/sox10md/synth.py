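"""Seeded synthetic immunostained-epidermis tiles with exact ground truth.

The generator emulates the statistical structure the margin-assessment
pipeline assumes on a Sox-10-stained skin section:

* a sinusoidally wavy epidermis band over dermis, with slide background
  above the corneal surface;
* junctional melanocytes placed as a Poisson process along the basal
  border's arc length, offset perpendicular within ±5 µm, rendered as dark
  brown nuclear ellipses;
* optional nests — clusters of ≥3 confluent (touching) nuclei;
* dermal distractor signals well outside the 10 µm junctional band, so the
  junctional filter has something to reject;
* additive Gaussian stain noise.

Every random draw flows from ``SceneSpec.seed``, so identical specs yield
byte-identical tiles. The emitted :class:`GroundTruth` carries the exact
epidermis mask, basal polyline with analytic arc length, centroid lists
with arc positions and nest ids, a nucleus instance label image, and
per-window counts on a fixed non-overlapping 0.5 mm grid — the oracles the
rest of the package is validated against.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

from .core import CalibratedImage, cumulative_arc_mm
from .errors import ConfigurationError, GenerationError

# Rendering palette (RGB). Dark nuclear chromogen on a pale counterstain.
SLIDE_RGB = (246, 245, 243)
EPIDERMIS_RGB = (206, 197, 223)
DERMIS_RGB = (229, 219, 234)
NUCLEUS_RGB = (84, 48, 28)

JUNCTIONAL_OFFSET_UM = 5.0  # max perpendicular offset of junctional nuclei
DERMAL_CLEARANCE_UM = 16.0  # distractors start this far below the basal border
WINDOW_GRID_MM = 0.5  # fixed generating window grid


@dataclass
class SceneSpec:
    """Parameters of one synthetic tile.

    All physical quantities are micrometres (or per-mm densities); pixel
    geometry follows from ``microns_per_pixel``. ``tile_size_px`` is
    ``(height, width)``.
    """

    tile_size_px: tuple[int, int] = (512, 1024)
    microns_per_pixel: float = 1.0
    epidermis_thickness_um: float = 60.0
    epidermis_waviness_um: float = 15.0
    waviness_period_um: float = 250.0
    junctional_density_per_mm: float = 20.0
    nest_count: int = 0
    nest_size_range: tuple[int, int] = (3, 5)
    dermal_distractor_density_per_mm2: float = 5.0
    nucleus_radius_um: tuple[float, float] = (2.5, 3.5)
    stain_noise_sd: float = 3.0
    min_nucleus_spacing_um: float = 0.0
    surface_margin_um: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.tile_size_px
        if h < 8 or w < 8:
            raise ConfigurationError(f"tile_size_px too small: {self.tile_size_px}")
        if self.microns_per_pixel <= 0:
            raise ConfigurationError("microns_per_pixel must be positive")
        if self.epidermis_thickness_um <= 0:
            raise ConfigurationError("epidermis_thickness_um must be positive")
        if self.epidermis_waviness_um < 0 or self.stain_noise_sd < 0:
            raise ConfigurationError("waviness and noise sd must be non-negative")
        if self.junctional_density_per_mm < 0:
            raise ConfigurationError("junctional_density_per_mm must be non-negative")
        if self.dermal_distractor_density_per_mm2 < 0:
            raise ConfigurationError("distractor density must be non-negative")
        if self.nest_count < 0:
            raise ConfigurationError("nest_count must be non-negative")
        lo, hi = self.nest_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(f"invalid nest_size_range {self.nest_size_range}")
        rlo, rhi = self.nucleus_radius_um
        if rlo <= 0 or rhi < rlo:
            raise ConfigurationError(f"invalid nucleus_radius_um {self.nucleus_radius_um}")
        # the band plus some dermis must fit in the tile
        needed_um = (
            self.surface_margin_um
            + self.epidermis_thickness_um
            + 2 * self.epidermis_waviness_um
            + DERMAL_CLEARANCE_UM
            + 3 * rhi
        )
        if needed_um >= h * self.microns_per_pixel:
            raise ConfigurationError(
                f"tile height {h}px at {self.microns_per_pixel} µm/px cannot hold "
                f"an epidermis band needing {needed_um:.0f} µm"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tile_size_px"] = list(self.tile_size_px)
        d["nest_size_range"] = list(self.nest_size_range)
        d["nucleus_radius_um"] = list(self.nucleus_radius_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SceneSpec keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("tile_size_px", "nest_size_range", "nucleus_radius_um"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact generating truth for one tile."""

    epidermis_mask: np.ndarray  # bool (H, W)
    basal_polyline: np.ndarray  # (N, 2) float px, ordered by x
    basal_arc_mm: np.ndarray  # (N,) cumulative arc length
    junctional_xy: np.ndarray  # (J, 2) float px
    junctional_arc_mm: np.ndarray  # (J,)
    junctional_nest_id: np.ndarray  # (J,) int, -1 = not in a nest
    junctional_radius_px: np.ndarray  # (J,)
    dermal_xy: np.ndarray  # (D, 2) float px
    dermal_radius_px: np.ndarray  # (D,)
    nuclei_labels: np.ndarray  # int32 (H, W); 1..J junctional, J+1.. dermal
    per_window_counts: list[int] = field(default_factory=list)

    @property
    def total_arc_mm(self) -> float:
        return float(self.basal_arc_mm[-1])

    @property
    def n_junctional(self) -> int:
        return len(self.junctional_xy)


def _basal_profile(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Float y of the basal border per integer x column."""
    h, w = spec.tile_size_px
    mpp = spec.microns_per_pixel
    x = np.arange(w, dtype=float)
    y0 = (spec.surface_margin_um + spec.epidermis_thickness_um) / mpp + spec.epidermis_waviness_um / mpp
    amp = spec.epidermis_waviness_um / mpp
    period_px = spec.waviness_period_um / mpp
    phase = rng.uniform(0, 2 * np.pi)
    return y0 + amp * np.sin(2 * np.pi * x / period_px + phase)


def _arc_interp(polyline: np.ndarray, arc_mm: np.ndarray, s_mm: np.ndarray):
    """Interpolate position, unit tangent and dermis-pointing normal at arc positions."""
    x = np.interp(s_mm, arc_mm, polyline[:, 0])
    y = np.interp(s_mm, arc_mm, polyline[:, 1])
    idx = np.clip(np.searchsorted(arc_mm, s_mm) - 1, 0, len(polyline) - 2)
    tan = polyline[idx + 1] - polyline[idx]
    tan = tan / np.linalg.norm(tan, axis=1, keepdims=True)
    # dermis is below the band (+y in image coordinates)
    normal = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    flip = normal[:, 1] < 0
    normal[flip] *= -1
    return np.stack([x, y], axis=1), tan, normal


def place_nests(
    polyline: np.ndarray,
    arc_mm: np.ndarray,
    nest_count: int,
    nest_size_range: tuple[int, int],
    radius_px: float,
    microns_per_pixel: float,
    rng: np.random.Generator,
    member_spacing_factor: float = 1.5,
):
    """Lay out nest clusters of confluent nuclei along the basal border.

    Members of one nest are placed at successive arc positions spaced
    ``member_spacing_factor * radius`` apart (< 2 radii, so rendered blobs
    overlap and the cluster is one confluent component), with small
    alternating perpendicular offsets within the junctional band.

    Returns ``(xy, arc, nest_id, radius_px)`` arrays; nest ids are 1-based
    and contiguous.
    """
    if nest_count == 0:
        return (np.zeros((0, 2)), np.zeros(0), np.zeros(0, dtype=int), np.zeros(0))
    total_mm = float(arc_mm[-1])
    lo, hi = nest_size_range
    sizes = rng.integers(lo, hi + 1, size=nest_count)
    spacing_mm = member_spacing_factor * radius_px * microns_per_pixel / 1000.0
    margin_mm = 0.02
    spans = sizes * spacing_mm
    if spans.max() + 2 * margin_mm > total_mm:
        raise GenerationError(
            f"nest of {sizes.max()} nuclei needs {spans.max():.3f} mm of basal border "
            f"but only {total_mm:.3f} mm is available"
        )
    # anchor nests without mutual overlap (rejection sampling)
    anchors: list[float] = []
    for span in spans:
        for _ in range(200):
            a = rng.uniform(margin_mm, total_mm - span - margin_mm)
            if all(a + span < b or a > b + s for b, s in zip(anchors, spans)):
                anchors.append(a)
                break
        else:
            raise GenerationError("could not place nests without overlap")
    xs, arcs, ids = [], [], []
    for nid, (a, size) in enumerate(zip(anchors, sizes), start=1):
        s = a + np.arange(size) * spacing_mm
        pos, _tan, normal = _arc_interp(polyline, arc_mm, s)
        # alternate small perpendicular offsets so the cluster looks nested;
        # kept below ~1 µm so radius jitter cannot open a gap between members
        off_um = ((np.arange(size) % 2) * 2 - 1) * rng.uniform(0.3, 1.0, size)
        pos = pos + normal * (off_um / microns_per_pixel)[:, None]
        xs.append(pos)
        arcs.append(s)
        ids.extend([nid] * size)
    xy = np.concatenate(xs)
    return xy, np.concatenate(arcs), np.asarray(ids, dtype=int), np.full(len(xy), radius_px)


def _render_nuclei(
    canvas: np.ndarray,
    labels: np.ndarray,
    xy: np.ndarray,
    radii_px: np.ndarray,
    rng: np.random.Generator,
    start_label: int,
) -> None:
    """Draw jittered dark ellipses; resolve overlaps by nearest centre."""
    h, w = labels.shape
    centres = {}
    for i, ((cx, cy), r) in enumerate(zip(xy, radii_px)):
        lab = start_label + i
        centres[lab] = (cx, cy)
        r1 = r * rng.uniform(0.8, 1.2)
        r2 = r * rng.uniform(0.8, 1.2)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, r1, r2, shape=(h, w), rotation=rot)
        prev = labels[rr, cc]
        take = prev == 0
        # contested pixels go to the closer centre, keeping instances disjoint
        contested = ~take
        if contested.any():
            pr, pc = rr[contested], cc[contested]
            d_new = (pc - cx) ** 2 + (pr - cy) ** 2
            d_old = np.empty_like(d_new, dtype=float)
            for j, lab_old in enumerate(prev[contested]):
                ox, oy = centres[lab_old]
                d_old[j] = (pc[j] - ox) ** 2 + (pr[j] - oy) ** 2
            win = d_new < d_old
            sel = np.where(contested)[0][win]
            labels[rr[sel], cc[sel]] = lab
        labels[rr[take], cc[take]] = lab
        canvas[rr, cc] = NUCLEUS_RGB


def generate_scene(spec: SceneSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one tile and its exact ground truth.

    Deterministic for a fixed ``spec`` (including seed): two calls return
    byte-identical rasters and identical truth arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.tile_size_px
    mpp = spec.microns_per_pixel

    y_basal = _basal_profile(spec, rng)
    thickness_px = spec.epidermis_thickness_um / mpp
    y_surface = y_basal - thickness_px

    polyline = np.stack([np.arange(w, dtype=float), y_basal], axis=1)
    arc_mm = cumulative_arc_mm(polyline, mpp)
    total_mm = float(arc_mm[-1])

    yy = np.arange(h, dtype=float)[:, None]
    epidermis = (yy >= y_surface[None, :]) & (yy <= y_basal[None, :])

    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = SLIDE_RGB
    dermis = yy > y_basal[None, :]
    canvas[dermis] = DERMIS_RGB
    canvas[epidermis] = EPIDERMIS_RGB

    r_lo, r_hi = spec.nucleus_radius_um

    # -- junctional background: Poisson along arc length, ±5 µm offset
    n_bg = rng.poisson(spec.junctional_density_per_mm * total_mm)
    s_bg = np.sort(rng.uniform(0, total_mm, n_bg))
    off_bg = rng.uniform(-JUNCTIONAL_OFFSET_UM, JUNCTIONAL_OFFSET_UM, n_bg)
    r_bg = rng.uniform(r_lo, r_hi, n_bg) / mpp
    pos, _tan, normal = _arc_interp(polyline, arc_mm, s_bg)
    xy_bg = pos + normal * (off_bg / mpp)[:, None]

    # -- nests
    nest_radius = float(np.mean(spec.nucleus_radius_um)) / mpp
    xy_nest, s_nest, nest_ids, r_nest = place_nests(
        polyline, arc_mm, spec.nest_count, spec.nest_size_range, nest_radius, mpp, rng
    )

    # -- optional hard-core thinning of background nuclei (keeps confluence
    # clusters an exclusive property of generated nests)
    if spec.min_nucleus_spacing_um > 0 and n_bg:
        min_px = spec.min_nucleus_spacing_um / mpp
        keep: list[int] = []
        kept_xy: list[np.ndarray] = list(xy_nest)
        for i in range(n_bg):
            p = xy_bg[i]
            ok = all(np.hypot(*(p - q)) >= min_px for q in kept_xy)
            if ok:
                keep.append(i)
                kept_xy.append(p)
        xy_bg, s_bg, off_bg, r_bg = xy_bg[keep], s_bg[keep], off_bg[keep], r_bg[keep]
        n_bg = len(keep)

    junct_xy = np.concatenate([xy_bg, xy_nest]) if len(xy_nest) else xy_bg
    junct_arc = np.concatenate([s_bg, s_nest]) if len(s_nest) else s_bg
    junct_nid = np.concatenate(
        [np.full(n_bg, -1, dtype=int), nest_ids]
    ) if len(nest_ids) else np.full(n_bg, -1, dtype=int)
    junct_r = np.concatenate([r_bg, r_nest]) if len(r_nest) else r_bg

    # sort by arc position for reproducible, readable exports
    order = np.argsort(junct_arc, kind="stable")
    junct_xy, junct_arc = junct_xy[order], junct_arc[order]
    junct_nid, junct_r = junct_nid[order], junct_r[order]

    # -- dermal distractors: Poisson over the dermis area beyond the band
    y_top = y_basal + DERMAL_CLEARANCE_UM / mpp
    depth_avail_px = np.clip(h - 1 - 2 * r_hi / mpp - y_top, 0, None)
    area_mm2 = float(depth_avail_px.sum()) * (mpp / 1000.0) ** 2
    n_derm = rng.poisson(spec.dermal_distractor_density_per_mm2 * area_mm2)
    xs = rng.integers(0, w, n_derm)
    ys = y_top[xs] + rng.uniform(0, 1, n_derm) * depth_avail_px[xs]
    dermal_xy = np.stack([xs.astype(float), ys], axis=1) if n_derm else np.zeros((0, 2))
    dermal_r = rng.uniform(r_lo, r_hi, n_derm) / mpp

    labels = np.zeros((h, w), dtype=np.int32)
    _render_nuclei(canvas, labels, junct_xy, junct_r, rng, start_label=1)
    _render_nuclei(canvas, labels, dermal_xy, dermal_r, rng, start_label=len(junct_xy) + 1)

    if spec.stain_noise_sd > 0:
        canvas += rng.normal(0, spec.stain_noise_sd, canvas.shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    n_windows = int(np.ceil(total_mm / WINDOW_GRID_MM)) if total_mm > 0 else 0
    per_window = [
        int(np.sum((junct_arc >= i * WINDOW_GRID_MM) & (junct_arc < (i + 1) * WINDOW_GRID_MM)))
        for i in range(n_windows)
    ]

    gt = GroundTruth(
        epidermis_mask=epidermis,
        basal_polyline=polyline,
        basal_arc_mm=arc_mm,
        junctional_xy=junct_xy,
        junctional_arc_mm=junct_arc,
        junctional_nest_id=junct_nid,
        junctional_radius_px=junct_r,
        dermal_xy=dermal_xy,
        dermal_radius_px=dermal_r,
        nuclei_labels=labels,
        per_window_counts=per_window,
    )
    return CalibratedImage(pixels, mpp, name=f"synthetic-seed{spec.seed}"), gt


def oracle_probability_map(gt: GroundTruth, spec: SceneSpec) -> "np.ndarray":
    """Idealised nuclear probability map: a Gaussian bump per nucleus.

    Each nucleus contributes ``exp(-d² / (2 (r/2)²))`` around its centroid
    (max-combined), so the map peaks at nuclear centres — the shape a
    well-trained detector produces, and what seeded watershed assumes.
    """
    h, w = gt.epidermis_mask.shape
    out = np.zeros((h, w), dtype=float)
    all_xy = np.concatenate([gt.junctional_xy, gt.dermal_xy]) if len(gt.dermal_xy) else gt.junctional_xy
    all_r = (
        np.concatenate([gt.junctional_radius_px, gt.dermal_radius_px])
        if len(gt.dermal_radius_px)
        else gt.junctional_radius_px
    )
    for (cx, cy), r in zip(all_xy, all_r):
        sig = max(r / 2.0, 1.0)
        ext = int(np.ceil(3 * r))
        x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, w)
        y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        d2 = ys[:, None] ** 2 + xs[None, :] ** 2
        bump = np.exp(-d2 / (2 * sig**2))
        bump[d2 > r**2] *= 0.3  # sharp shoulder at the nuclear edge
        np.maximum(out[y0:y1, x0:x1], bump, out=out[y0:y1, x0:x1])
    return out


# ---------------------------------------------------------------------------
# fixture export / import
# ---------------------------------------------------------------------------

def export_fixture(image: CalibratedImage, gt: GroundTruth, directory, spec: SceneSpec | None = None) -> dict:
    """Write a fixture directory and return its manifest.

    Layout: ``image.tiff`` (resolution metadata embedded),
    ``epidermis_mask.png`` (0/255), ``nuclei_labels.png`` (uint16),
    ``centroids.csv`` and ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    px_per_cm = 10000.0 / image.microns_per_pixel
    tifffile.imwrite(
        directory / "image.tiff",
        image.pixels,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        description=json.dumps({"microns_per_pixel": image.microns_per_pixel}),
    )
    iio.imwrite(directory / "epidermis_mask.png", (gt.epidermis_mask.astype(np.uint8) * 255))
    iio.imwrite(directory / "nuclei_labels.png", gt.nuclei_labels.astype(np.uint16))

    rows = []
    for (x, y), s, nid in zip(gt.junctional_xy, gt.junctional_arc_mm, gt.junctional_nest_id):
        rows.append({"x_px": x, "y_px": y, "compartment": "junctional", "arc_mm": s,
                     "nest_id": int(nid) if nid > 0 else ""})
    for (x, y) in gt.dermal_xy:
        rows.append({"x_px": x, "y_px": y, "compartment": "dermal", "arc_mm": "", "nest_id": ""})
    pd.DataFrame(rows, columns=["x_px", "y_px", "compartment", "arc_mm", "nest_id"]).to_csv(
        directory / "centroids.csv", index=False, float_format="%.17g"
    )

    np.save(directory / "basal_polyline.npy", gt.basal_polyline)
    np.savetxt(directory / "junctional_radius_px.txt", gt.junctional_radius_px)
    np.savetxt(directory / "dermal_radius_px.txt", gt.dermal_radius_px)
    np.savetxt(directory / "per_window_counts.txt", np.asarray(gt.per_window_counts, dtype=int), fmt="%d")

    checksum = hashlib.sha256(image.pixels.tobytes()).hexdigest()
    manifest = {
        "microns_per_pixel": image.microns_per_pixel,
        "checksum_sha256": checksum,
        "n_junctional": int(gt.n_junctional),
        "n_dermal": int(len(gt.dermal_xy)),
        "total_arc_mm": gt.total_arc_mm,
    }
    if spec is not None:
        manifest["spec"] = spec.to_dict()
        manifest["seed"] = spec.seed
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_fixture(directory) -> tuple[CalibratedImage, GroundTruth, dict]:
    """Load a fixture directory written by :func:`export_fixture`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    mpp = manifest["microns_per_pixel"]
    pixels = tifffile.imread(directory / "image.tiff")
    mask = iio.imread(directory / "epidermis_mask.png") > 0
    labels = iio.imread(directory / "nuclei_labels.png").astype(np.int32)

    df = pd.read_csv(directory / "centroids.csv")
    junct = df[df.compartment == "junctional"]
    derm = df[df.compartment == "dermal"]
    nest_id = junct.nest_id.fillna(-1).replace("", -1).astype(int).to_numpy() if len(junct) else np.zeros(0, dtype=int)

    polyline = np.load(directory / "basal_polyline.npy")
    arc = cumulative_arc_mm(polyline, mpp)
    def _floats(name: str) -> np.ndarray:
        return np.array([float(v) for v in (directory / name).read_text().split()])

    jr = _floats("junctional_radius_px.txt")
    dr = _floats("dermal_radius_px.txt")
    pwc = _floats("per_window_counts.txt").astype(int).tolist()

    gt = GroundTruth(
        epidermis_mask=mask,
        basal_polyline=polyline,
        basal_arc_mm=arc,
        junctional_xy=junct[["x_px", "y_px"]].to_numpy(dtype=float).reshape(-1, 2),
        junctional_arc_mm=junct.arc_mm.to_numpy(dtype=float) if len(junct) else np.zeros(0),
        junctional_nest_id=nest_id,
        junctional_radius_px=jr[: len(junct)],
        dermal_xy=derm[["x_px", "y_px"]].to_numpy(dtype=float).reshape(-1, 2),
        dermal_radius_px=dr[: len(derm)],
        nuclei_labels=labels,
        per_window_counts=pwc,
    )
    image = CalibratedImage(pixels, mpp, name=directory.name)
    return image, gt, manifest
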