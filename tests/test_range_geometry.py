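"""Alpha-shapes, realm classification, clipping, and geodesic areas."""

import numpy as np
import pytest
import shapely
import shapely.affinity
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import Delaunay

from lewontin import range_geometry as rg
from lewontin.errors import (
    DegenerateGeometryError,
    EmptyRangeError,
    InvalidArgumentError,
    InvalidGeometryError,
)


class TestAlphaShape:
    def test_triangle_recovered_for_large_alpha(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        geom = rg.alpha_shape(pts, alpha=10.0)
        assert geom.area == pytest.approx(0.5)

    def test_square_with_center_hits_convex_hull_limit(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], float)
        geom = rg.alpha_shape(pts, alpha=10.0)
        assert geom.area == pytest.approx(1.0)

    def test_annulus_develops_hole_and_shrinks(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, 500)
        r = rng.uniform(3, 5, 500)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        shape = rg.alpha_shape(pts, alpha=1.2)
        hull = rg.convex_hull(pts)
        polys = shape.geoms if shape.geom_type == "MultiPolygon" else [shape]
        assert sum(len(p.interiors) for p in polys) >= 1
        assert shape.area < hull.area
        # brute-force oracle: shoelace sum over kept triangles equals the
        # union area when triangles tile without overlap
        tri = Delaunay(pts)
        keep = rg._circumradii(pts, tri.simplices) <= 1.2
        def tri_area(p):
            (x0, y0), (x1, y1), (x2, y2) = p
            return abs((x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)) / 2

        oracle = sum(tri_area(p) for p in pts[tri.simplices[keep]])
        assert shape.area == pytest.approx(oracle, rel=1e-9)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 10, size=(120, 2))
        # sliver triangles can have enormous circumradii, so the hull limit
        # needs alpha well beyond the point-set diameter
        areas = [rg.alpha_shape(pts, a).area for a in (0.8, 1.5, 3.0, 1e6)]
        assert all(a1 <= a2 + 1e-12 for a1, a2 in zip(areas, areas[1:]))
        hull = rg.convex_hull(pts)
        assert areas[-1] == pytest.approx(hull.area, rel=1e-9)
        # vertex sets match in the convex-hull limit
        big = rg.alpha_shape(pts, 1e6)
        assert set(map(tuple, np.round(np.asarray(big.exterior.coords), 9))) == set(
            map(tuple, np.round(np.asarray(hull.exterior.coords), 9))
        )

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            rg.alpha_shape(np.array([[0.0, 0.0], [1.0, 1.0]]), 1.0)
        collinear = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateGeometryError):
            rg.alpha_shape(collinear, 1.0)


class TestRealmAndClipping:
    land = shapely.box(0, 0, 10, 10)

    def test_all_on_land_is_terrestrial(self):
        occ = rg.OccurrenceSet("t", np.array([[1.0, 1.0], [2.0, 3.0]]))
        assert rg.classify_realm(occ, self.land) == "terrestrial"

    def test_minority_on_land_is_marine(self):
        pts = np.array([[1.0, 1.0], [20.0, 1.0], [21.0, 2.0], [22.0, 3.0], [23.0, 4.0]])
        assert rg.classify_realm(rg.OccurrenceSet("m", pts), self.land) == "marine"

    def test_exact_tie_is_terrestrial(self):
        pts = np.array([[1.0, 1.0], [2.0, 2.0], [20.0, 1.0], [21.0, 1.0]])
        assert rg.classify_realm(rg.OccurrenceSet("t", pts), self.land) == "terrestrial"

    def test_terrestrial_clip_is_identity_on_land(self):
        square = shapely.box(2, 2, 8, 8)
        out = rg.clip_range(square, "terrestrial", self.land)
        assert out.equals(square)

    def test_terrestrial_clip_halves_overhanging_square(self):
        square = shapely.box(5, 0, 15, 10)
        out = rg.clip_range(square, "terrestrial", self.land)
        assert out.area == pytest.approx(square.area / 2)

    def test_marine_clip_removes_island(self):
        ocean_range = shapely.box(-5, -5, 15, 15)
        island = shapely.box(0, 0, 4, 4)
        out = rg.clip_range(ocean_range, "marine", island)
        # shoelace oracle on the constructed fixture
        assert out.area == pytest.approx(20 * 20 - 4 * 4)
        assert out.area <= ocean_range.area

    def test_empty_intersection_raises(self):
        far = shapely.box(100, 40, 110, 50)
        with pytest.raises(EmptyRangeError):
            rg.clip_range(far, "terrestrial", self.land)


class TestPolygonArea:
    def test_equatorial_cell_matches_band_formula(self):
        area = rg.polygon_area_km2(shapely.box(0, 0, 1, 1))
        expected = rg.EARTH_RADIUS_KM**2 * np.radians(1.0) * np.sin(np.radians(1.0))
        assert area == pytest.approx(expected, rel=1e-6)
        assert area == pytest.approx(12364, rel=0.005)

    def test_hemisphere(self):
        area = rg.polygon_area_km2(shapely.box(-180, 0, 180, 90))
        assert area == pytest.approx(2 * np.pi * rg.EARTH_RADIUS_KM**2, rel=1e-9)

    def test_longitude_rotation_invariance(self):
        poly = shapely.Polygon([(10, 10), (30, 15), (25, 40), (5, 30)])
        a1 = rg.polygon_area_km2(poly)
        a2 = rg.polygon_area_km2(shapely.affinity.translate(poly, xoff=37.0))
        assert abs(a1 - a2) / a1 < 1e-9

    def test_antimeridian_straddling_polygon(self):
        poly = shapely.Polygon([(10, 10), (30, 15), (25, 40), (5, 30)])
        reference = rg.polygon_area_km2(poly)
        shifted = shapely.affinity.translate(poly, xoff=160.0)  # lons 165..190
        wrapped = shapely.Polygon(
            [(lon - 360 if lon > 180 else lon, lat) for lon, lat in shifted.exterior.coords]
        )
        assert rg.polygon_area_km2(wrapped) == pytest.approx(reference, rel=1e-9)
        split = rg.split_at_antimeridian(wrapped)
        assert split.geom_type == "MultiPolygon"
        assert rg.polygon_area_km2(split) == pytest.approx(reference, rel=1e-6)

    def test_additive_over_disjoint_parts(self):
        a = shapely.box(0, 0, 1, 1)
        b = shapely.box(5, 5, 6, 6)
        multi = shapely.MultiPolygon([a, b])
        assert rg.polygon_area_km2(multi) == pytest.approx(
            rg.polygon_area_km2(a) + rg.polygon_area_km2(b), rel=1e-12
        )

    def test_self_intersection_rejected(self):
        bowtie = shapely.Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(InvalidGeometryError):
            rg.polygon_area_km2(bowtie)

    @given(
        lon=st.floats(-170, 170),
        lat=st.floats(-60, 60),
        width=st.floats(0.5, 8),
    )
    @settings(max_examples=25, deadline=None)
    def test_clipping_never_increases_area(self, lon, lat, width):
        square = shapely.box(lon, lat, lon + width, lat + width)
        land = shapely.box(lon + width / 3, lat, lon + 2 * width, lat + 2 * width)
        clipped = rg.clip_range(square, "terrestrial", land)
        assert rg.polygon_area_km2(clipped) <= rg.polygon_area_km2(square) * (1 + 1e-9)


class TestEstimateRange:
    def test_buffer_fallback_for_degenerate_points(self):
        occ = rg.OccurrenceSet("sparse", np.array([[0.0, 0.0], [0.5, 0.5]]))
        result = rg.estimate_range(occ)
        assert np.isnan(result.alpha_used)
        assert result.area_km2 > np.pi * 100.0**2 * 0.8  # at least ~one disc

    def test_buffer_radius_scaling(self):
        geom = rg.buffer_points_km(np.array([[0.0, 0.0]]), radius_km=100.0)
        area = rg.polygon_area_km2(geom)
        assert area == pytest.approx(np.pi * 100.0**2, rel=0.05)

    def test_full_pipeline_with_land(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform([0, 0], [20, 20], size=(300, 2))
        occ = rg.OccurrenceSet("sp", pts)
        land = shapely.box(-5, -5, 25, 25)
        result = rg.estimate_range(occ, land=land)
        assert result.realm == "terrestrial"
        assert 0 < result.area_km2 <= 5.1e8
        assert result.alpha_used == rg.DEFAULT_ALPHA["terrestrial"]

    def test_invalid_alpha_rejected(self):
        occ = rg.OccurrenceSet("x", np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(InvalidArgumentError):
            rg.alpha_shape(occ, alpha=0.0)
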