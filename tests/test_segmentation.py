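import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfmoco.errors import SegmentationParseError
from perfmoco.segmentation import (
    SegmentationFrame,
    SegmentationSet,
    circle_contour,
    circumcircle,
    myocardium_mask,
    rasterize_contour,
    read_segmentation,
    section_masks,
    write_segmentation,
)


def point_in_polygon(px, py, contour):
    """Brute-force even-odd ray casting oracle (horizontal ray to +x)."""
    inside = False
    n = len(contour)
    for i in range(n):
        x1, y1 = contour[i]
        x2, y2 = contour[(i + 1) % n]
        if (y1 <= py) != (y2 <= py):
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if xi > px:
                inside = not inside
    return inside


def brute_force_mask(contour, shape):
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = point_in_polygon(float(c), float(r), contour)
    return mask


def star_frame(center=(16.0, 16.0), endo_r=6.0, epi_r=10.0, ip_angle=0.0):
    rays = [
        (
            center[0] + epi_r * math.cos(ip_angle + k * 2 * math.pi / 3),
            center[1] + epi_r * math.sin(ip_angle + k * 2 * math.pi / 3),
        )
        for k in range(3)
    ]
    return SegmentationFrame(
        image_ref="frame0000",
        star_center=center,
        star_rays=rays,
        endocardium=circle_contour(center, endo_r, 40),
        epicardium=circle_contour(center, epi_r, 40),
    )


class TestRasterize:
    def test_square_area(self):
        square = np.array([(5.5, 5.5), (15.5, 5.5), (15.5, 15.5), (5.5, 15.5)])
        mask = rasterize_contour(square, (32, 32))
        assert mask.sum() == 100
        np.testing.assert_array_equal(mask, brute_force_mask(square, (32, 32)))

    def test_triangle_matches_oracle(self):
        tri = np.array([(0.0, 0.0), (0.0, 4.0), (4.0, 0.0)])
        mask = rasterize_contour(tri, (8, 8))
        np.testing.assert_array_equal(mask, brute_force_mask(tri, (8, 8)))

    def test_two_point_contour_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            rasterize_contour(np.array([(0.0, 0.0), (1.0, 1.0)]), (8, 8))

    def test_collinear_contour_warns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask = rasterize_contour(
                np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]), (8, 8)
            )
        assert not mask.any()

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_random_polygons_match_point_in_polygon_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        # vertices off the pixel-centre lattice so boundary ties cannot occur
        contour = rng.uniform(0.25, 15.65, size=(n, 2)) + 0.013
        mask = rasterize_contour(contour, (16, 16))
        np.testing.assert_array_equal(mask, brute_force_mask(contour, (16, 16)))


class TestMyocardiumMask:
    def test_annulus_area(self):
        frame = star_frame(endo_r=6.0, epi_r=10.0)
        mask = myocardium_mask(frame, (32, 32))
        expected = math.pi * (10.0**2 - 6.0**2)
        assert abs(mask.sum() - expected) < 0.12 * expected

    def test_identical_contours_empty(self):
        center = (16.0, 16.0)
        frame = SegmentationFrame(
            "f", center, [(26.0, 16.0), (11.0, 24.7), (11.0, 7.3)],
            circle_contour(center, 8.0), circle_contour(center, 8.0),
        )
        assert not myocardium_mask(frame, (32, 32)).any()

    def test_non_nested_contours_warn(self):
        frame = SegmentationFrame(
            "f", (16.0, 16.0), [(26.0, 16.0), (11.0, 24.7), (11.0, 7.3)],
            circle_contour((24.0, 16.0), 6.0),      # endo sticking out of epi
            circle_contour((16.0, 16.0), 8.0),
        )
        with pytest.warns(UserWarning, match="not nested"):
            myocardium_mask(frame, (32, 32))


class TestCircumcircle:
    def test_unit_circle(self):
        center, r = circumcircle((0, 1), (1, 0), (0, -1))
        assert center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_equilateral_centroid(self):
        pts = [(math.cos(a), math.sin(a)) for a in (0, 2 * math.pi / 3, 4 * math.pi / 3)]
        center, r = circumcircle(*pts)
        centroid = (sum(p[0] for p in pts) / 3, sum(p[1] for p in pts) / 3)
        assert center == pytest.approx(centroid, abs=1e-12)

    def test_equidistance_property(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.uniform(-50, 50, size=(3, 2))
            d1, d2 = pts[1] - pts[0], pts[2] - pts[0]
            if abs(d1[0] * d2[1] - d1[1] * d2[0]) < 1e-3:
                continue
            (cx, cy), r = circumcircle(*pts)
            for px, py in pts:
                assert math.hypot(px - cx, py - cy) == pytest.approx(r, rel=1e-9)

    def test_collinear_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            circumcircle((0, 0), (1, 1), (2, 2))


class TestSectionMasks:
    def test_default_is_twelve_sections(self):
        result = section_masks(star_frame(), (32, 32))
        assert result.n_sections == 12
        assert result.angular_increment == pytest.approx(30.0)

    def test_six_sections(self):
        result = section_masks(star_frame(), (32, 32), n_sections=6)
        assert result.n_sections == 6
        assert result.angular_increment == pytest.approx(60.0)

    def test_partition(self):
        result = section_masks(star_frame(), (32, 32))
        union = np.zeros((32, 32), dtype=int)
        for m in result.sections:
            union += m
        np.testing.assert_array_equal(union > 0, result.myocardium_mask)
        assert union.max() == 1      # pairwise disjoint

    def test_rotation_permutes_labels(self):
        # rotating anatomy and RV insertion by one angular increment
        # relabels a circularly symmetric myocardium by one position
        base = section_masks(star_frame(ip_angle=0.1), (40, 40))
        rotated = section_masks(
            star_frame(ip_angle=0.1 + math.pi / 6), (40, 40)
        )
        mismatch = 0
        for k in range(12):
            mismatch += np.sum(rotated.sections[k] != base.sections[(k + 1) % 12])
        assert mismatch <= 0.02 * base.myocardium_mask.sum() * 12

    def test_empty_myocardium_errors(self):
        center = (16.0, 16.0)
        frame = SegmentationFrame(
            "f", center, [(26.0, 16.0), (11.0, 24.7), (11.0, 7.3)],
            circle_contour(center, 8.0), circle_contour(center, 8.0),
        )
        with pytest.raises(ValueError, match="empty"):
            section_masks(frame, (32, 32))

    def test_first_section_starts_at_rv_insertion_ray(self):
        frame = star_frame(ip_angle=0.0)     # RV_ip due +x of centre
        result = section_masks(frame, (32, 32))
        rows, cols = np.nonzero(result.sections[0])
        ang = np.degrees(np.arctan2(rows - 16.0, cols - 16.0)) % 360.0
        assert ang.max() < 30.5 and ang.min() >= 0.0


def random_segset(rng, n_frames=3):
    frames = []
    for i in range(n_frames):
        center = tuple(rng.uniform(10, 20, size=2))
        frames.append(
            SegmentationFrame(
                image_ref=f"frame{i:04d}",
                star_center=center,
                star_rays=[tuple(rng.uniform(0, 30, size=2)) for _ in range(3)],
                endocardium=rng.uniform(0, 30, size=(int(rng.integers(3, 12)), 2)),
                epicardium=rng.uniform(0, 30, size=(int(rng.integers(3, 12)), 2)),
            )
        )
    return SegmentationSet(
        frames,
        rv_peak_index=int(rng.integers(0, n_frames)),
        lv_peak_index=int(rng.integers(0, n_frames)),
        slice_level=int(rng.integers(0, 3)),
    )


class TestXmlDialect:
    def test_round_trip_identity(self, tmp_path, rng):
        for trial in range(10):
            segset = random_segset(rng, n_frames=int(rng.integers(1, 5)))
            path = tmp_path / f"seg{trial}.xml"
            write_segmentation(segset, path)
            loaded = read_segmentation(path)
            assert loaded.rv_peak_index == segset.rv_peak_index
            assert loaded.lv_peak_index == segset.lv_peak_index
            assert loaded.slice_level == segset.slice_level
            for a, b in zip(segset.frames, loaded.frames):
                assert a.image_ref == b.image_ref
                assert a.star_center == pytest.approx(b.star_center)
                np.testing.assert_allclose(a.star_rays, b.star_rays)
                np.testing.assert_allclose(a.endocardium, b.endocardium)
                np.testing.assert_allclose(a.epicardium, b.epicardium)

    def test_empty_frame_list_valid(self, tmp_path):
        segset = SegmentationSet([], lv_peak_index=None)
        path = tmp_path / "empty.xml"
        write_segmentation(segset, path)
        assert read_segmentation(path).frames == []

    def test_lv_peak_preserved(self, tmp_path, rng):
        segset = random_segset(rng)
        path = tmp_path / "peaks.xml"
        write_segmentation(segset, path)
        assert read_segmentation(path).lv_peak_index == segset.lv_peak_index

    def test_missing_star_is_parse_error(self, tmp_path):
        path = tmp_path / "nostar.xml"
        path.write_text(
            "<workset><frame image='f'>"
            "<contour role='endocardium'><point x='0' y='0'/><point x='1' y='0'/>"
            "<point x='0' y='1'/></contour>"
            "<contour role='epicardium'><point x='0' y='0'/><point x='2' y='0'/>"
            "<point x='0' y='2'/></contour>"
            "</frame></workset>"
        )
        with pytest.raises(SegmentationParseError, match="star"):
            read_segmentation(path)

    def test_error_names_element_path(self, tmp_path):
        path = tmp_path / "badrole.xml"
        path.write_text(
            "<workset><frame><star x='1' y='1'>"
            "<point x='0' y='0'/><point x='1' y='0'/><point x='0' y='1'/></star>"
            "<contour role='weird'><point x='0' y='0'/></contour>"
            "</frame></workset>"
        )
        with pytest.raises(SegmentationParseError, match=r"frame\[0\]"):
            read_segmentation(path)

    def test_non_finite_coordinate_errors(self, tmp_path, rng):
        segset = random_segset(rng)
        segset.frames[0].endocardium[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            write_segmentation(segset, tmp_path / "nan.xml")

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=8,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, points):
        path = tmp_path_factory.mktemp("prop") / "seg.xml"
        contour = np.array(points)
        frame = SegmentationFrame(
            "frame0000", (1.0, 2.0),
            [(0.0, 0.0), (1.5, -2.5), (3.25, 4.125)],
            contour, contour + 1.0,
        )
        segset = SegmentationSet([frame], rv_peak_index=0, lv_peak_index=0)
        write_segmentation(segset, path)
        loaded = read_segmentation(path)
        np.testing.assert_array_equal(loaded.frames[0].endocardium, contour)
        np.testing.assert_array_equal(loaded.frames[0].epicardium, contour + 1.0)
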