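"""End-to-end slide and cohort drivers.

``run_slide`` takes one calibrated image (or a synthetic fixture
directory), produces the epidermis mask, basal contours, separated
nucleus instances, the junctional subset, density windows, nest calls and
the slide-level call, and writes the report JSON, windows/instances/nests
CSVs and the heat-map overlay PNG.

``run_cohort`` evaluates a manifest of slides against recorded truth
columns and emits confusion tables, the ROC over the cutoff grid, the
AUC, and the Youden-selected cutoff.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig
from .core import CalibratedImage
from .density import SlideReport, compute_density_profile, render_heatmap, slide_call
from .epidermis import extract_basal_contour, segment_epidermis, tissue_from_image
from .errors import ConfigurationError, DegenerateInputError, InputError
from .nests import find_nests, slide_nest_flag, combined_call
from .nuclei import filter_junctional, instances_from_labels, junctional_only, separate_instances
from .segmenter import PixelSegmenter
from .synth import load_fixture
from . import evalstats

log = logging.getLogger("sox10md")


# ---------------------------------------------------------------------------
# image loading with calibration precedence: TIFF metadata < sidecar < flag
# ---------------------------------------------------------------------------

def _mpp_from_tiff(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            desc = page.description
            if desc:
                try:
                    meta = json.loads(desc)
                    if "microns_per_pixel" in meta:
                        return float(meta["microns_per_pixel"])
                except (ValueError, TypeError):
                    pass
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None:
                num, den = res.value
                px_per_unit = num / den
                unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 3) if unit is None else unit.value, 10000.0)
                if px_per_unit > 0:
                    return unit_um / px_per_unit
    except Exception:
        return None
    return None


def load_image(path, mpp_flag: float | None = None) -> CalibratedImage:
    """Load a TIFF/PNG image resolving calibration from, in increasing
    precedence: TIFF resolution metadata, a ``<stem>.calibration.json`` /
    ``calibration.json`` sidecar, and an explicit flag."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    pixels = iio.imread(path) if path.suffix.lower() != ".tiff" and path.suffix.lower() != ".tif" else tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    mpp = None
    if path.suffix.lower() in (".tif", ".tiff"):
        mpp = _mpp_from_tiff(path)
    for sidecar in (path.with_suffix(".calibration.json"), path.parent / "calibration.json"):
        if sidecar.exists():
            mpp = float(json.loads(sidecar.read_text())["microns_per_pixel"])
    if mpp_flag is not None:
        mpp = mpp_flag
    if mpp is None:
        raise ConfigurationError(f"no calibration found for {path}; pass --mpp")
    return CalibratedImage(pixels, mpp, name=path.stem)


# ---------------------------------------------------------------------------
# slide driver
# ---------------------------------------------------------------------------

def analyse_slide(
    image: CalibratedImage,
    config: PipelineConfig,
    oracle=None,
) -> tuple[SlideReport, dict]:
    """Run the full analysis on one loaded image.

    ``oracle`` is an optional synthetic ground truth; with
    ``config.oracle_masks`` it supplies the epidermis mask and nucleus
    instances directly, bypassing the trained detectors.

    Returns the report and an artefact dict (contours, instances, labels,
    windows, nests) for export or inspection.
    """
    t0 = time.perf_counter()
    mpp = image.microns_per_pixel

    if config.oracle_masks:
        if oracle is None:
            raise ConfigurationError("oracle_masks set but no ground truth supplied")
        epi_mask = segment_epidermis(image, oracle_mask=oracle.epidermis_mask)
    else:
        if config.epidermis_checkpoint is None:
            raise ConfigurationError("no epidermis checkpoint and oracle backend off")
        seg = PixelSegmenter.load(config.epidermis_checkpoint)
        epi_mask = segment_epidermis(image, seg, seg.config.binarisation_threshold)

    tissue = tissue_from_image(image)
    contours = extract_basal_contour(
        epi_mask, mpp, tissue_mask=None if config.orientation_hint else tissue,
        orientation_hint=config.orientation_hint,
    )
    report = SlideReport(slide_id=image.name, config_echo=_echo(config))
    artefacts = {"contours": contours, "instances": [], "labels": None,
                 "windows": [], "nests": [], "epidermis_mask": epi_mask}
    if not contours:
        report.status = "no-epidermis"
        report.slide_call = "indeterminate"
        return report, artefacts

    if config.oracle_masks:
        instances, labels = instances_from_labels(oracle.nuclei_labels, mpp)
    else:
        if config.nuclei_checkpoint is None:
            raise ConfigurationError("no nuclei checkpoint and oracle backend off")
        nseg = PixelSegmenter.load(config.nuclei_checkpoint)
        prob = nseg.predict_probability(image)
        instances, labels = separate_instances(prob, config.separation)

    filter_junctional(instances, contours, config.junctional)
    junctional = junctional_only(instances)

    windows = []
    for c in contours:
        inst_c = [i for i in junctional if i.contour_id == c.segment_id]
        windows.extend(compute_density_profile(inst_c, c, config.cutoffs, config.stride_mm))
    max_density, call = slide_call(windows, config.cutoffs)

    nest_calls = find_nests(instances, labels, config.nests, mpp)

    report.windows = windows
    report.max_density = max_density
    report.slide_call = call
    report.nest_flag = slide_nest_flag(nest_calls)
    report.n_instances = len(instances)
    report.n_junctional = len(junctional)
    report.n_excluded = len(instances) - len(junctional)
    report.n_contours = len(contours)
    artefacts.update(instances=instances, labels=labels, windows=windows, nests=nest_calls)
    log.info(
        "slide %s: %d contours, %d/%d junctional nuclei, max density %.1f, call %s (%.2fs)",
        image.name, len(contours), len(junctional), len(instances),
        max_density, call, time.perf_counter() - t0,
    )
    return report, artefacts


def _echo(config: PipelineConfig) -> dict:
    d = config.to_dict()
    d["version"] = __version__
    return d


def run_slide(path, config: PipelineConfig, output_dir=None) -> SlideReport:
    """Analyse one slide from disk and write all artefacts.

    ``path`` may be an image file or a synthetic fixture directory
    (containing ``manifest.json``); fixture directories also provide the
    oracle ground truth for ``oracle_masks`` runs.
    """
    path = Path(path)
    oracle = None
    if path.is_dir() and (path / "manifest.json").exists():
        image, oracle, _manifest = load_fixture(path)
        if config.microns_per_pixel is not None:
            image.microns_per_pixel = config.microns_per_pixel
    else:
        image = load_image(path, config.microns_per_pixel)

    report, art = analyse_slide(image, config, oracle=oracle)

    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{image.name}.report.json").write_text(json.dumps(report.to_dict(), indent=2))
    pd.DataFrame([w.as_row() for w in report.windows]).to_csv(
        outdir / f"{image.name}.windows.csv", index=False)
    pd.DataFrame([i.as_row() for i in art.get("instances", [])]).to_csv(
        outdir / f"{image.name}.instances.csv", index=False)
    pd.DataFrame([n.as_row() for n in art.get("nests", [])]).to_csv(
        outdir / f"{image.name}.nests.csv", index=False)
    overlay = render_heatmap(image, art["contours"], report.windows)
    iio.imwrite(outdir / f"{image.name}.overlay.png", overlay)
    if art.get("labels") is not None:
        iio.imwrite(outdir / f"{image.name}.labels.png",
                    np.asarray(art["labels"], dtype=np.uint16))
    from .epidermis import contours_to_geojson

    (outdir / f"{image.name}.contours.geojson").write_text(
        json.dumps(contours_to_geojson(art["contours"])))
    return report


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def run_cohort(manifest_csv, config: PipelineConfig, output_dir=None) -> dict:
    """Batch-evaluate a cohort manifest.

    The manifest CSV needs columns ``slide_id`` and ``path`` plus truth
    columns ``gt_or`` (0/1 original report), ``gt_md_count`` (manual count
    in the densest 0.5 mm window) and optionally ``nest_gt`` (0/1).
    Produces per-slide reports plus confusion tables for AI vs GT-OR, AI
    vs GT-MD, GT-MD vs GT-OR, the ROC grid, AUC, and the selected cutoff.
    """
    manifest_csv = Path(manifest_csv)
    if not manifest_csv.exists():
        raise InputError(f"manifest not found: {manifest_csv}")
    df = pd.read_csv(manifest_csv)
    for col in ("slide_id", "path", "gt_or", "gt_md_count"):
        if col not in df.columns:
            raise InputError(f"manifest missing required column {col!r}")

    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, rec in df.iterrows():
        slide_path = Path(str(rec["path"]))
        if not slide_path.is_absolute():
            slide_path = manifest_csv.parent / slide_path
        report = run_slide(slide_path, config, output_dir=outdir / "slides")
        ai_positive = report.slide_call == "positive" or (
            config.borderline_positive and report.slide_call == "borderline")
        rows.append({
            "slide_id": rec["slide_id"],
            "ai_max_density": report.max_density,
            "ai_call": report.slide_call,
            "ai_positive": ai_positive,
            "ai_nest": report.nest_flag,
            "ai_combined": combined_call(report.slide_call, report.nest_flag),
            "gt_or": bool(rec["gt_or"]),
            "gt_md_count": int(rec["gt_md_count"]),
            "gt_md_positive": int(rec["gt_md_count"]) >= config.cutoffs.red_min,
            "nest_gt": bool(rec["nest_gt"]) if "nest_gt" in df.columns else None,
            "count_concordant": evalstats.count_agreement(
                int(round(report.max_density)), int(rec["gt_md_count"]), config.agreement),
        })
    calls = pd.DataFrame(rows)
    calls.to_csv(outdir / "calls.csv", index=False)

    metrics: dict = {"n_slides": len(calls), "version": __version__, "config": _echo(config)}

    def _table(pred, truth, name):
        try:
            metrics[name] = evalstats.summarize(evalstats.compare_calls(pred, truth))
        except Exception as e:  # single-class cohorts: report status, not numbers
            metrics[name] = {"status": f"undefined: {e}"}

    _table(calls.ai_positive, calls.gt_or, "ai_md_vs_gt_or")
    _table(calls.ai_positive, calls.gt_md_positive, "ai_md_vs_gt_md")
    _table(calls.gt_md_positive, calls.gt_or, "gt_md_vs_gt_or")
    if calls.nest_gt.notna().all():
        _table(calls.ai_nest, calls.nest_gt, "ai_nest_vs_gt_nest")
        _table(calls.ai_combined, calls.gt_or, "ai_combined_vs_gt_or")

    try:
        points = evalstats.roc_curve(calls.ai_max_density, calls.gt_or, config.roc)
        metrics["auc_ai_vs_gt_or"] = evalstats.auc(points)
        metrics["selected_cutoff"] = evalstats.select_cutoff(points)
        pd.DataFrame(
            [{"cutoff": p.cutoff, "tpr": p.tpr, "fpr": p.fpr, "youden": p.youden} for p in points]
        ).to_csv(outdir / "roc.csv", index=False)
    except Exception as e:
        metrics["roc_status"] = f"undefined: {e}"

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
    return metrics
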