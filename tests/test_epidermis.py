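"""Tiling, segmentation thresholding, and basal-contour extraction."""

import numpy as np
import pytest

from sox10md.core import CalibratedImage, ProbabilityMap
from sox10md.epidermis import (
    extract_basal_contour,
    reassemble,
    segment_epidermis,
    tile_image,
    tissue_from_image,
    train_epidermis_segmenter,
)
from sox10md.errors import ConfigurationError, OrientationError
from sox10md.segmenter import SegmenterConfig, split_fixtures

from conftest import small_spec


def _img(h, w, mpp=1.0, fill=128):
    return CalibratedImage(np.full((h, w, 3), fill, dtype=np.uint8), mpp)


class TestTiling:
    def test_single_patch(self):
        patches, offsets, _ = tile_image(_img(512, 512), 512, 0)
        assert len(patches) == 1 and offsets == [(0, 0)]

    def test_two_patches_round_trip(self):
        img = CalibratedImage(
            np.random.default_rng(0).integers(0, 255, (512, 1024, 3), dtype=np.uint8), 1.0
        )
        patches, offsets, padded = tile_image(img, 512, 0)
        assert len(patches) == 2
        out = reassemble(patches, offsets, padded, out_shape=img.shape)
        np.testing.assert_array_equal(out.astype(np.uint8), img.pixels)

    def test_overlap_coverage(self):
        # oracle: accumulate a coverage-count raster; every pixel covered >= 1
        img = _img(700, 700)
        patches, offsets, padded = tile_image(img, 512, 128)
        cover = np.zeros(padded)
        for p, (y, x) in zip(patches, offsets):
            cover[y : y + 512, x : x + 512] += 1
        assert (cover[:700, :700] >= 1).all()

    def test_small_image_padded(self):
        patches, _, padded = tile_image(_img(100, 100), 512, 0)
        assert len(patches) == 1 and patches[0].shape[:2] == (512, 512)
        assert padded == (512, 512)

    def test_identity_reassembly_no_overlap(self):
        img = CalibratedImage(
            np.random.default_rng(1).integers(0, 255, (600, 900, 3), dtype=np.uint8), 1.0
        )
        patches, offsets, padded = tile_image(img, 512, 0)
        out = reassemble(patches, offsets, padded, out_shape=img.shape)
        np.testing.assert_array_equal(out.astype(np.uint8), img.pixels)


class TestSegmentation:
    def test_tie_rule_at_threshold(self):
        pm = ProbabilityMap(np.full((16, 16), 0.5), 1.0)
        mask = segment_epidermis(_img(16, 16), probability_map=pm, threshold=0.5)
        assert mask.all()  # probability >= threshold => epidermis

    def test_constant_above_threshold(self):
        pm = ProbabilityMap(np.full((8, 8), 0.7), 1.0)
        assert segment_epidermis(_img(8, 8), probability_map=pm, threshold=0.5).all()

    def test_oracle_identity(self, default_scene):
        _, img, gt = default_scene
        mask = segment_epidermis(img, oracle_mask=gt.epidermis_mask)
        np.testing.assert_array_equal(mask, gt.epidermis_mask)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        pm = ProbabilityMap(rng.uniform(0, 1, (64, 64)), 1.0)
        img = _img(64, 64)
        prev = segment_epidermis(img, probability_map=pm, threshold=0.3)
        for thr in (0.5, 0.7, 0.9):
            cur = segment_epidermis(img, probability_map=pm, threshold=thr)
            assert not np.any(cur & ~prev)  # raising the threshold never adds pixels
            prev = cur

    def test_requires_some_backend(self):
        with pytest.raises(ConfigurationError):
            segment_epidermis(_img(8, 8))


class TestBasalContour:
    def test_straight_band_length(self):
        # 2 mm wide straight band at 1 µm/px, analytic length 2.0 mm
        mask = np.zeros((200, 2000), dtype=bool)
        mask[50:120, :] = True
        contours = extract_basal_contour(mask, 1.0, orientation_hint="surface=top")
        assert len(contours) == 1
        assert contours[0].length_mm == pytest.approx(2.0, rel=0.01)
        # basal side is the lower boundary
        assert contours[0].points[:, 1].mean() == pytest.approx(119, abs=1.5)

    def test_empty_mask(self):
        assert extract_basal_contour(np.zeros((50, 50), dtype=bool), 1.0,
                                     orientation_hint="surface=top") == []

    def test_sinusoidal_fixture_within_1pct(self, default_scene):
        _, img, gt = default_scene
        contours = extract_basal_contour(
            gt.epidermis_mask, img.microns_per_pixel, tissue_mask=tissue_from_image(img)
        )
        assert len(contours) == 1
        assert contours[0].length_mm == pytest.approx(gt.total_arc_mm, rel=0.01)

    def test_contour_near_mask_boundary(self, default_scene):
        from scipy.spatial import cKDTree

        _, img, gt = default_scene
        contours = extract_basal_contour(
            gt.epidermis_mask, img.microns_per_pixel, tissue_mask=tissue_from_image(img)
        )
        d, _ = cKDTree(gt.basal_polyline).query(contours[0].points)
        assert d.max() <= 1.5

    def test_rotation_invariance(self, default_scene):
        _, img, gt = default_scene
        mpp = img.microns_per_pixel
        tissue = tissue_from_image(img)
        base = extract_basal_contour(gt.epidermis_mask, mpp, tissue_mask=tissue)[0].length_mm
        rot = extract_basal_contour(
            np.rot90(gt.epidermis_mask), mpp, tissue_mask=np.rot90(tissue)
        )[0].length_mm
        assert rot == pytest.approx(base, rel=0.01)

    def test_fragment_filter_drops_specks(self):
        mask = np.zeros((100, 600), dtype=bool)
        mask[40:70, :500] = True  # 0.5 mm fragment
        mask[40:45, 550:590] = True  # 40 µm speck: below the 100 µm cutoff
        contours = extract_basal_contour(mask, 1.0, orientation_hint="surface=top")
        assert len(contours) == 1

    def test_orientation_required(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[20:40, :] = True
        with pytest.raises(OrientationError):
            extract_basal_contour(mask, 1.0)

    def test_dermis_side_from_tissue_mask(self):
        # band with tissue below only -> basal contour at the bottom edge
        mask = np.zeros((100, 300), dtype=bool)
        mask[30:60, :] = True
        tissue = np.zeros_like(mask)
        tissue[30:, :] = True  # dermis below the band
        c = extract_basal_contour(mask, 1.0, tissue_mask=tissue)
        assert len(c) == 1
        assert c[0].points[:, 1].mean() == pytest.approx(59, abs=1.5)
        assert c[0].normals[:, 1].mean() > 0.9  # normals point into the dermis


class TestTraining:
    def test_split_arithmetic_and_determinism(self):
        tr1, va1 = split_fixtures(10, 0.2, seed=5)
        tr2, va2 = split_fixtures(10, 0.2, seed=5)
        assert (tr1, va1) == (tr2, va2)
        assert len(va1) == 2 and len(tr1) == 8
        assert sorted(tr1 + va1) == list(range(10))

    def test_trained_beats_untrained_iou(self, trained_segmenters):
        epi_result, _ = trained_segmenters
        assert epi_result.val_score > epi_result.baseline_score
        assert len(epi_result.loss_history) == 5

    def test_empty_fixture_set_rejected(self):
        with pytest.raises(ConfigurationError):
            train_epidermis_segmenter([], [], SegmenterConfig())

    def test_checkpoint_round_trip(self, tmp_path, trained_segmenters, training_set):
        from sox10md.segmenter import PixelSegmenter

        epi_result, _ = trained_segmenters
        path = tmp_path / "epi.joblib"
        epi_result.segmenter.save(path)
        loaded = PixelSegmenter.load(path)
        img = training_set[0][0]
        np.testing.assert_allclose(
            loaded.predict_probability(img).values,
            epi_result.segmenter.predict_probability(img).values,
        )


class TestGeoJSONExport:
    def test_linestring_round_trip(self):
        import json
        from sox10md.epidermis import contours_to_geojson

        mask = np.zeros((100, 400), dtype=bool)
        mask[30:60, :] = True
        contours = extract_basal_contour(mask, 1.0, orientation_hint="surface=top")
        gj = json.loads(json.dumps(contours_to_geojson(contours)))
        assert gj["type"] == "FeatureCollection"
        feat = gj["features"][0]
        assert feat["geometry"]["type"] == "LineString"
        assert feat["properties"]["length_mm"] == pytest.approx(
            contours[0].length_mm)
        assert len(feat["geometry"]["coordinates"]) == len(contours[0].points)
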