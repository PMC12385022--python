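"""Corner extraction: exact rectangles, rotated quadrilaterals, invariances."""

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

import spondylograde as sg
from spondylograde import geometry as geo


def rect_mask(shape, top, left, height, width, label=1):
    m = np.zeros(shape, dtype=np.uint8)
    m[top:top + height, left:left + width] = label
    return m


def rasterize_quad(vertices, shape):
    """vertices: list of (x, y) in pixel-centre coordinates."""
    m = np.zeros(shape, dtype=bool)
    xs = [v[0] for v in vertices]
    ys = [v[1] for v in vertices]
    rr, cc = draw_polygon(ys, xs, shape=shape)
    m[rr, cc] = True
    return m


class TestLargestComponent:
    def test_single_blob_unchanged(self):
        m = rect_mask((40, 40), 5, 5, 10, 10)
        comp = geo.largest_component(m, 1)
        assert np.array_equal(comp, m.astype(bool))

    def test_picks_largest_by_exhaustive_pixel_count(self):
        m = np.zeros((50, 50), dtype=np.uint8)
        m[2:12, 2:12] = 3        # 100 px
        m[40:45, 40:41] = 3      # 5 px
        comp = geo.largest_component(m, 3)
        assert comp.sum() == 100
        assert comp[5, 5] and not comp[42, 40]

    def test_missing_label_raises_named_error(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        with pytest.raises(geo.MissingStructureError, match="L2"):
            geo.largest_component(m, 2)

    def test_eight_connectivity_joins_diagonal(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:5, 2:5] = 1
        m[5, 5] = 1  # touches only diagonally
        comp = geo.largest_component(m, 1)
        assert comp.sum() == 10


class TestCornerPoints:
    def test_axis_aligned_rectangle_exact(self):
        m = rect_mask((64, 64), 10, 10, 20, 40)
        c = geo.corner_points(m.astype(bool), anterior_direction="left")
        points = {c.upper_anterior, c.upper_posterior, c.lower_anterior, c.lower_posterior}
        assert points == {(10.0, 10.0), (49.0, 10.0), (10.0, 29.0), (49.0, 29.0)}
        # anterior = decreasing x
        assert c.upper_anterior == (10.0, 10.0)
        assert c.upper_posterior == (49.0, 10.0)

    @pytest.mark.parametrize("angle_deg", [45.0, 20.0, -30.0])
    def test_rotated_rectangle_within_1p5_px(self, angle_deg):
        theta = np.radians(angle_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        base = np.array([[-20, -10], [20, -10], [20, 10], [-20, 10]], dtype=float)
        true_vertices = base @ rot.T + np.array([60.0, 60.0])
        m = rasterize_quad(true_vertices, (120, 120))
        c = geo.corner_points(m, anterior_direction="left")
        got = np.array(c.points())
        # exhaustive nearest-vertex matching: each true vertex has one
        # extracted corner within 1.5 px
        for tv in true_vertices:
            d = np.linalg.norm(got - tv, axis=1).min()
            assert d <= 1.5, (angle_deg, tv, got)

    def test_flipping_anterior_swaps_labels_not_points(self):
        m = rect_mask((64, 64), 10, 10, 20, 40).astype(bool)
        left = geo.corner_points(m, "left")
        right = geo.corner_points(m, "right")
        assert set(left.points()) == set(right.points())
        assert left.upper_anterior == right.upper_posterior
        assert left.lower_anterior == right.lower_posterior

    def test_small_component_rejected(self):
        m = rect_mask((20, 20), 5, 5, 3, 3).astype(bool)
        with pytest.raises(geo.DegenerateComponentError, match="area"):
            geo.corner_points(m)

    def test_points_inside_component_bounding_box(self, untilted_phantom):
        for label in range(1, 7):
            comp = geo.largest_component(untilted_phantom.mask, label)
            ys, xs = np.nonzero(comp)
            c = geo.corner_points(comp)
            for x, y in c.points():
                assert xs.min() - 1e-9 <= x <= xs.max() + 1e-9
                assert ys.min() - 1e-9 <= y <= ys.max() + 1e-9


class TestSacrumTopCorners:
    def test_rectangular_standin_exact_top_corners(self):
        m = rect_mask((64, 64), 30, 12, 16, 36, label=6)
        c = geo.sacrum_top_corners(m, "left")
        assert c.upper_anterior == (12.0, 30.0)
        assert c.upper_posterior == (47.0, 30.0)
        assert c.lower_anterior is None

    def test_trapezoid_top_corners_match_bruteforce_nearest_vertex(self):
        # narrower top: top edge x in [20, 40], bottom x in [10, 50]
        verts = [(20.0, 10.0), (40.0, 10.0), (50.0, 30.0), (10.0, 30.0)]
        m = rasterize_quad(verts, (64, 64)).astype(np.uint8) * 6
        c = geo.sacrum_top_corners(m, "left")
        hull = geo._hull_vertices(m == 6)
        rect = geo._min_area_rect(hull)
        # brute-force: for each upper rect corner, nearest hull vertex
        upper = rect[np.argsort(rect[:, 1])[:2]]
        expected = set()
        for rc in upper:
            d = np.linalg.norm(hull - rc, axis=1)
            expected.add(tuple(hull[d.argmin()]))
        assert {c.upper_anterior, c.upper_posterior} == expected

    def test_missing_sacrum_raises(self):
        with pytest.raises(geo.MissingStructureError, match="S1"):
            geo.sacrum_top_corners(np.zeros((20, 20), dtype=np.uint8))


class TestExtractAll:
    def test_phantom_all_levels_within_2px(self, untilted_phantom):
        lm = geo.extract_all_landmarks(untilted_phantom.mask, "left")
        assert lm.n_points() == 22
        for level, truth in untilted_phantom.truth_corners.corners.items():
            for pt, pg in zip(truth.points(), lm.corners[level].points()):
                assert np.hypot(pt[0] - pg[0], pt[1] - pg[1]) <= 2.0

    def test_empty_mask_flags_everything(self):
        lm = geo.extract_all_landmarks(np.zeros((32, 32), dtype=np.uint8))
        assert lm.corners == {}
        assert set(lm.missing) == {"L1", "L2", "L3", "L4", "L5", "S1"}

    def test_partial_mask_reports_found_and_missing(self, untilted_phantom):
        partial = np.where(np.isin(untilted_phantom.mask, [4, 5, 6]),
                           untilted_phantom.mask, 0).astype(np.uint8)
        lm = geo.extract_all_landmarks(partial)
        assert set(lm.corners) == {"L4", "L5", "S1"}
        assert set(lm.missing) == {"L1", "L2", "L3"}

    def test_translation_equivariance(self):
        m = rect_mask((80, 80), 10, 10, 14, 30).astype(bool)
        c0 = geo.corner_points(m)
        shifted = np.roll(np.roll(m, 7, axis=0), 11, axis=1)
        c1 = geo.corner_points(shifted)
        for p0, p1 in zip(c0.points(), c1.points()):
            assert p1 == (p0[0] + 11, p0[1] + 7)

    def test_rot90_equivariance_with_direction_remap(self):
        """Rotating the mask 90° maps the same physical corners.

        Under np.rot90 (counter-clockwise), a point (x, y) in an HxW image
        maps to (y, W-1-x); image-up becomes image-left, so the extracted
        point *set* of the rotated component is the mapped point set.
        """
        m = rect_mask((60, 80), 12, 20, 14, 34).astype(bool)
        c0 = geo.corner_points(m, "left")
        w = m.shape[1]
        rotated = np.rot90(m)
        c1 = geo.corner_points(rotated, "left")
        mapped = {(y, w - 1 - x) for x, y in c0.points()}
        assert set(c1.points()) == mapped

    def test_json_roundtrip(self, untilted_phantom, tmp_path):
        lm = geo.extract_all_landmarks(untilted_phantom.mask)
        path = tmp_path / "lm.json"
        lm.to_json(path)
        back = geo.LandmarkSet.from_json(path)
        assert back.to_dict() == lm.to_dict()


def test_corner_convergence_with_resolution():
    """Rasterized quad corners approach the true vertices as resolution grows."""
    theta = np.radians(18.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    base = np.array([[-1.6, -0.8], [1.6, -0.8], [1.6, 0.8], [-1.6, 0.8]])
    errs = []
    for scale in (12.0, 36.0):
        verts = (base * scale) @ rot.T + np.array([3 * scale, 3 * scale])
        m = rasterize_quad(verts, (int(6 * scale), int(6 * scale)))
        c = geo.corner_points(m)
        got = np.array(c.points())
        err = max(np.linalg.norm(got - tv, axis=1).min() for tv in verts)
        errs.append(err)
    assert errs[1] <= errs[0] + 0.25
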