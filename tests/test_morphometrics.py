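"""Calibration, projected leaf area, heights and the shape-descriptor traits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoshoot import geometry, morphometrics, segmentation, synthetic
from phenoshoot.morphometrics import CameraCalibration
from phenoshoot.segmentation import PlantMask

from oracles import eccentricity_bruteforce


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return PlantMask(m)


def _block_mask(shape, r0, r1, c0, c1, view="top"):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return PlantMask(m, view)


class TestCalibration:
    def test_topview_constant_at_origin(self):
        assert morphometrics.topview_constant(0.0) == 0.061936

    def test_topview_constant_at_1000(self):
        # 9.937e-5 * 1000 + 0.061936, evaluated by hand
        assert morphometrics.topview_constant(1000.0) == pytest.approx(0.161306, abs=1e-12)

    def test_strictly_increasing_in_yax(self):
        ys = np.linspace(0, 2000, 50)
        ks = [morphometrics.topview_constant(y) for y in ys]
        assert np.all(np.diff(ks) > 0)

    def test_negative_yax_rejected(self):
        with pytest.raises(ValueError):
            morphometrics.topview_constant(-1.0)

    def test_linear_side_constant_reading(self):
        calib = CameraCalibration.linear_side_constant(0.273)
        assert calib.side_linear_factor == 0.273
        assert calib.side_area_factor == pytest.approx(0.273**2)


class TestProjectedLeafArea:
    def test_side_views_only(self):
        empty = PlantMask(np.zeros((40, 40), bool), "top")
        s0 = _block_mask((40, 40), 0, 25, 0, 40, "side0")  # 1000 px
        s90 = _block_mask((40, 40), 0, 25, 0, 40, "side90")
        area = morphometrics.projected_leaf_area(empty, s0, s90)
        assert area == pytest.approx(2000 * 0.273)

    def test_top_view_at_yax_zero(self):
        top = _block_mask((40, 40), 0, 25, 0, 40, "top")  # 1000 px
        empty0 = PlantMask(np.zeros((40, 40), bool), "side0")
        empty90 = PlantMask(np.zeros((40, 40), bool), "side90")
        area = morphometrics.projected_leaf_area(top, empty0, empty90)
        assert area == pytest.approx(1000 * 0.061936)

    def test_all_empty_warns_and_returns_zero(self):
        e = PlantMask(np.zeros((5, 5), bool))
        with pytest.warns(UserWarning):
            assert morphometrics.projected_leaf_area(e, e, e) == 0.0

    def test_yax_is_mean_side_centroid_row(self):
        top = _block_mask((60, 60), 10, 20, 10, 20, "top")  # 100 px
        s0 = _block_mask((60, 60), 10, 21, 28, 33, "side0")  # centroid row 15
        s90 = _block_mask((60, 60), 30, 41, 28, 33, "side90")  # centroid row 35
        k = morphometrics.topview_constant(25.0)
        expected = 100 * k + (s0.pixel_count + s90.pixel_count) * 0.273
        assert morphometrics.projected_leaf_area(top, s0, s90) == pytest.approx(expected)


class TestShapeRatios:
    def test_plus_sign_hand_counted(self):
        """Plus-shaped mask: ratios against hand-derived corner geometry.

        11x3 horizontal and 3x11 vertical bar overlapping in 3x3: 57 px.
        Corner hull is the octagon of area 121 - 4*8 = 89; the enclosing
        circle is centred on the centre with r^2 = 5.5^2 + 1.5^2 = 32.5.
        """
        m = np.zeros((11, 11), dtype=bool)
        m[4:7, 0:11] = True
        m[0:11, 4:7] = True
        mask = PlantMask(m)
        assert mask.pixel_count == 57
        compact, coverage = morphometrics.compactness_and_coverage(mask)
        assert compact == pytest.approx(57 / 89, rel=1e-12)
        assert coverage == pytest.approx(57 / (math.pi * 32.5), rel=1e-9)

    def test_filled_disc_compactness_near_one(self):
        from skimage.draw import disk as draw_disk

        m = np.zeros((61, 61), dtype=bool)
        rr, cc = draw_disk((30, 30), 25)
        m[rr, cc] = True
        compact, coverage = morphometrics.compactness_and_coverage(PlantMask(m))
        assert 0.95 <= compact <= 1.0
        assert 0.9 <= coverage <= 1.0

    def test_coverage_never_exceeds_compactness(self, rng):
        for _ in range(20):
            m = rng.random((30, 30)) > 0.6
            if m.sum() < 3:
                continue
            compact, coverage = morphometrics.compactness_and_coverage(PlantMask(m))
            assert 0 < coverage <= compact <= 1.0

    @given(st.integers(0, 10_000))
    def test_ordering_chain(self, seed):
        """fg area <= corner-hull area <= circle area; calliper <= diameter."""
        r = np.random.default_rng(seed)
        m = r.random((25, 25)) > 0.7
        if m.sum() < 3:
            return
        mask = PlantMask(m)
        pts = mask.coords_xy()
        corners = morphometrics._corner_points(pts)
        hull_area = geometry.polygon_area(geometry.convex_hull(corners))
        _, radius = geometry.min_enclosing_circle(corners)
        assert mask.pixel_count <= hull_area + 1e-9
        assert hull_area <= math.pi * radius**2 + 1e-9
        assert geometry.calliper_length(pts) <= 2 * radius + 1e-9


class TestEccentricity:
    def test_filled_disc_is_radially_symmetric(self):
        from skimage.draw import disk as draw_disk

        m = np.zeros((61, 61), dtype=bool)
        rr, cc = draw_disk((30, 30), 25)
        m[rr, cc] = True
        assert morphometrics.eccentricity(PlantMask(m)) < 0.05

    def test_two_to_one_ellipse(self):
        from skimage.draw import ellipse as draw_ellipse

        m = np.zeros((101, 101), dtype=bool)
        rr, cc = draw_ellipse(50, 50, 20, 40)
        m[rr, cc] = True
        assert morphometrics.eccentricity(PlantMask(m)) == pytest.approx(math.sqrt(3) / 2, abs=0.01)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_moment_matrix_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = r.random((20, 20)) > 0.5
        mask = PlantMask(m)
        assert morphometrics.eccentricity(mask) == pytest.approx(eccentricity_bruteforce(mask.coords_xy()), rel=1e-12)

    def test_degenerate_raises(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3, 3:6] = True  # collinear: zero variance across the line
        with pytest.raises(ValueError):
            morphometrics.eccentricity(PlantMask(m))


class TestHeights:
    def test_bare_stem_height(self):
        m = np.zeros((250, 30), dtype=bool)
        m[30:230, 14:17] = True  # 200 rows tall
        f = CameraCalibration().side_linear_factor
        max_h, lig_h = morphometrics.heights([PlantMask(m, "side0")])
        assert max_h == pytest.approx(200 * f)
        assert lig_h == pytest.approx(max_h)  # no divergence point

    def test_generator_plant_heights(self, default_plant):
        _, images, truth = default_plant
        f = CameraCalibration().side_linear_factor
        masks = [PlantMask(images.true_masks[v], v) for v in ("side0", "side90")]
        max_h, lig_h = morphometrics.heights(masks)
        assert max_h == pytest.approx(truth.max_height_px * f, rel=0.01)
        assert lig_h == pytest.approx(truth.ligule_height_px * f, rel=0.05)

    def test_empty_masks_raise(self):
        with pytest.raises(ValueError):
            morphometrics.heights([PlantMask(np.zeros((5, 5), bool))])


class TestTraitAssembly:
    def test_full_record_invariants(self, default_plant):
        _, images, truth = default_plant
        masks = {v: PlantMask(images.true_masks[v], v) for v in ("top", "side0", "side90")}
        tr = morphometrics.compute_shoot_traits(
            masks["top"], masks["side0"], masks["side90"], top_image=images.top,
            nir_pair=(images.nir["side0"], images.nir["side90"]),
        )
        assert 0 < tr.surface_coverage <= tr.compactness <= 1.0
        assert tr.calliper_length <= 2 * tr.min_circle_radius + 1e-9
        assert tr.hull_area <= math.pi * tr.min_circle_radius**2 * 1.0001
        assert tr.ligule_height <= tr.max_height
        assert 0 <= tr.eccentricity < 1
        assert tr.projected_leaf_area > 0
        assert tr.senescent_fraction == pytest.approx(0.04, abs=0.005)
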