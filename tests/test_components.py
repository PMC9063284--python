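"""Component layer: entropy, rasterization, network, focal/zonal statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Polygon, box

from walkability.components import (LandscapeBundle, LandUseComposition,
                                    compute_components,
                                    extract_true_intersections,
                                    focal_buffer_mean, land_use_entropy,
                                    rasterize_area_fraction,
                                    rasterize_point_count,
                                    sample_at_centroids, snap_network,
                                    zonal_mean, LANDUSE_CLASSES, COMPONENTS)
from walkability.grids import GridLayer

from conftest import focal_mean_loop_oracle


# -- land-use entropy -----------------------------------------------------

class TestLandUseEntropy:
    def test_perfect_mix_is_one(self):
        comp = LandUseComposition(np.full(5, 0.2), total_relevant_area=1e4)
        assert land_use_entropy(comp) == 1.0

    def test_single_class_is_zero(self):
        comp = LandUseComposition([1, 0, 0, 0, 0], total_relevant_area=1e4)
        assert land_use_entropy(comp) == 0.0

    def test_two_even_classes(self):
        # direct evaluation of -sum p ln p / ln 5 for p = (1/2, 1/2)
        expected = np.log(2) / np.log(5)
        comp = LandUseComposition([0.5, 0.5, 0, 0, 0], total_relevant_area=1.0)
        assert land_use_entropy(comp) == pytest.approx(expected, abs=1e-15)

    def test_no_relevant_area_scores_zero(self):
        comp = LandUseComposition(np.zeros(5), total_relevant_area=0.0)
        assert land_use_entropy(comp) == 0.0

    def test_negative_share_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            LandUseComposition([-0.1, 0.4, 0.3, 0.2, 0.2])

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            LandUseComposition([0.3, 0.3, 0.3, 0.3, 0.3])

    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5)
           .filter(lambda p: sum(p) > 1e-6))
    @settings(derandomize=True, max_examples=60)
    def test_entropy_bounds_and_extremes(self, raw):
        p = np.asarray(raw) / sum(raw)
        h = land_use_entropy(LandUseComposition(p, total_relevant_area=1.0))
        assert 0.0 <= h <= 1.0
        if np.allclose(p, 0.2):
            assert h == pytest.approx(1.0, abs=1e-12)
        if (p > 0).sum() == 1:
            assert h == 0.0


# -- rasterization --------------------------------------------------------

class TestRasterizeAreaFraction:
    def test_polygon_covering_exactly_one_cell(self):
        grid = GridLayer((0, 0), 25.0, np.zeros((4, 4)))
        out = rasterize_area_fraction(box(25, 50, 50, 75), grid)
        expected = np.zeros((4, 4))
        expected[2, 1] = 1.0
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_half_cell_axis_aligned(self):
        grid = GridLayer((0, 0), 25.0, np.zeros((2, 2)))
        out = rasterize_area_fraction(box(0, 0, 12.5, 25), grid)
        assert out.values[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_random_polygons_match_oversampling_oracle(self):
        rng = np.random.default_rng(3)
        grid = GridLayer((0, 0), 25.0, np.zeros((6, 6)))
        polys = []
        for _ in range(4):
            cx, cy = rng.uniform(10, 140, 2)
            pts = []
            for ang in np.sort(rng.uniform(0, 2 * np.pi, 6)):
                r = rng.uniform(8, 35)
                pts.append((cx + r * np.cos(ang), cy + r * np.sin(ang)))
            poly = Polygon(pts)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
        out = rasterize_area_fraction(polys, grid)
        # 64x oversampling oracle: fraction of subcell centres inside
        from shapely.ops import unary_union
        import shapely
        union = unary_union(polys)
        k = 64
        sub = (np.arange(k) + 0.5) / k * 25.0
        for i in range(6):
            for j in range(6):
                xs = j * 25.0 + sub
                ys = i * 25.0 + sub
                gx, gy = np.meshgrid(xs, ys)
                frac = shapely.contains_xy(union, gx.ravel(), gy.ravel()).mean()
                assert out.values[i, j] == pytest.approx(frac, abs=0.02)


class TestRasterizePointCount:
    def test_point_at_cell_centre(self):
        grid = GridLayer((0, 0), 25.0, np.zeros((3, 3)))
        out = rasterize_point_count(np.array([[37.5, 62.5]]), grid)
        assert out.values[2, 1] == 1
        assert out.values.sum() == 1

    def test_shared_edge_half_open_rule(self):
        grid = GridLayer((0, 0), 25.0, np.zeros((2, 2)))
        out = rasterize_point_count(np.array([[25.0, 10.0]]), grid)
        # x = 25 belongs to the cell owning [25, 50)
        assert out.values[0, 1] == 1
        assert out.values[0, 0] == 0

    def test_poisson_scatter_total_preserved(self):
        rng = np.random.default_rng(11)
        grid = GridLayer((0, 0), 25.0, np.zeros((8, 8)))
        pts = rng.uniform(-50, 250, size=(300, 2))
        inside = ((pts >= 0) & (pts < 200)).all(axis=1)
        out = rasterize_point_count(pts, grid)
        assert out.values.sum() == inside.sum()


# -- street network -------------------------------------------------------

def _cross(cls_n="street", cls_s="street", cls_e="street", cls_w="street"):
    c = (50.0, 50.0)
    return [
        (LineString([c, (50, 100)]), cls_n),
        (LineString([c, (50, 0)]), cls_s),
        (LineString([c, (100, 50)]), cls_e),
        (LineString([c, (0, 50)]), cls_w),
    ]


class TestTrueIntersections:
    def test_four_leg_crossing(self):
        pts = extract_true_intersections(_cross())
        np.testing.assert_allclose(pts, [[50.0, 50.0]])

    def test_t_junction_counts_straight_node_does_not(self):
        t = _cross()[:3]                       # 3 legs
        assert len(extract_true_intersections(t)) == 1
        straight = _cross()[:2]                # 2 legs through-node
        assert len(extract_true_intersections(straight)) == 0

    def test_highway_arm_reduces_degree(self):
        # one arm inaccessible: degree 3, still an intersection
        assert len(extract_true_intersections(_cross(cls_n="highway"))) == 1
        # two arms inaccessible: degree 2, no longer an intersection
        assert len(extract_true_intersections(
            _cross(cls_n="highway", cls_e="highway"))) == 0

    def test_brute_force_degree_oracle(self):
        rng = np.random.default_rng(5)
        nodes = rng.uniform(0, 1000, size=(12, 2)).round(1)
        roads = []
        for _ in range(25):
            i, j = rng.choice(12, 2, replace=False)
            roads.append((LineString([nodes[i], nodes[j]]), "street"))
        got = extract_true_intersections(roads, noding_check_tolerance=0)
        deg = {}
        for geom, _ in roads:
            for p in (geom.coords[0], geom.coords[-1]):
                deg[p] = deg.get(p, 0) + 1
        expected = sorted(p for p, d in deg.items() if d >= 3)
        assert sorted(map(tuple, got)) == expected

    def test_unnoded_network_raises_with_coordinates(self):
        roads = [(LineString([(0, 0), (50, 50)]), "street"),
                 (LineString([(50.0001, 50.0001), (100, 100)]), "street"),
                 (LineString([(50, 50), (0, 100)]), "street")]
        with pytest.raises(ValueError, match="not noded"):
            extract_true_intersections(roads)

    def test_snap_network_repairs_near_coincident_endpoints(self):
        roads = [(LineString([(0, 0), (50, 50)]), "street"),
                 (LineString([(50.0001, 50.0001), (100, 100)]), "street"),
                 (LineString([(50, 50), (0, 100)]), "street")]
        snapped = snap_network(roads, tolerance=0.01)
        pts = extract_true_intersections(snapped)
        assert len(pts) == 1


# -- focal statistics -----------------------------------------------------

class TestFocalBufferMean:
    def test_constant_raster_unchanged(self, small_grid):
        layer = small_grid.like(np.full((10, 10), 3.7))
        for r in (150.0, 500.0):
            np.testing.assert_allclose(
                focal_buffer_mean(layer, r).values, layer.values, rtol=1e-12)

    def test_single_count_density_per_km2(self):
        vals = np.zeros((41, 41))
        vals[20, 20] = 1.0
        layer = GridLayer((0, 0), 25.0, vals, "count")
        out = focal_buffer_mean(layer, 150.0)
        # kernel cells with centre within 150 m at 25 m cells
        kernel_n = sum(1 for dy in range(-6, 7) for dx in range(-6, 7)
                       if (dx * dx + dy * dy) * 625 <= 150 ** 2)
        assert kernel_n == 113
        expected = (1.0 / kernel_n) / (625 / 1e6)
        assert out.values[20, 20] == pytest.approx(expected, rel=1e-12)
        assert out.semantics == "density"

    @pytest.mark.parametrize("radius", [150.0, 500.0, 1000.0])
    def test_matches_loop_oracle_exactly(self, radius):
        rng = np.random.default_rng(int(radius))
        layer = GridLayer((0, 0), 25.0, rng.uniform(0, 10, (23, 31)), "value")
        got = focal_buffer_mean(layer, radius).values
        np.testing.assert_array_equal(got, focal_mean_loop_oracle(layer, radius))

    def test_subcell_radius_warns_and_is_identity(self, small_grid):
        with pytest.warns(UserWarning, match="identity"):
            out = focal_buffer_mean(small_grid, 10.0)
        np.testing.assert_array_equal(out.values, small_grid.values)

    def test_commutes_with_scalar_multiplication(self, small_grid):
        a = focal_buffer_mean(small_grid.like(3.0 * small_grid.values), 150.0)
        b = focal_buffer_mean(small_grid, 150.0)
        np.testing.assert_allclose(a.values, 3.0 * b.values, rtol=1e-12)

    def test_peak_value_non_increasing_in_radius(self):
        vals = np.zeros((21, 21))
        vals[10, 10] = 100.0
        layer = GridLayer((0, 0), 25.0, vals, "value")
        peaks = [focal_buffer_mean(layer, r).values[10, 10]
                 for r in (50, 100, 200, 400, 500)]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))


# -- sampling & zonal -----------------------------------------------------

class TestSampling:
    def test_cell_centre_and_boundary(self, small_grid):
        v = sample_at_centroids(small_grid, np.array([[37.5, 37.5],
                                                      [25.0, 25.0]]))
        assert v[0] == small_grid.values[1, 1]
        assert v[1] == small_grid.values[1, 1]   # half-open: edge owns upper cell

    def test_random_points_match_index_arithmetic(self, small_grid):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 250, (40, 2))
        got = sample_at_centroids(small_grid, pts)
        exp = [small_grid.values[int(y // 25), int(x // 25)] for x, y in pts]
        np.testing.assert_array_equal(got, exp)

    def test_outside_point_is_missing(self, small_grid):
        v = sample_at_centroids(small_grid, np.array([[-5.0, 10.0]]))
        assert np.isnan(v[0])


class TestZonalMean:
    def test_full_extent_zone_gives_global_mean(self, small_grid):
        out = zonal_mean(small_grid, [("all", box(0, 0, 250, 250))])
        assert out["all"] == pytest.approx(small_grid.values.mean(), rel=1e-12)

    def test_half_plane_zones_match_loop_oracle(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        layer = GridLayer((0, 0), 25.0, vals)
        zones = [("west", box(0, 0, 125, 250)), ("east", box(125, 0, 250, 250))]
        out = zonal_mean(layer, zones)
        assert out["west"] == pytest.approx(vals[:, :5].mean())
        assert out["east"] == pytest.approx(vals[:, 5:].mean())

    def test_sliver_zone_is_missing(self, small_grid):
        out = zonal_mean(small_grid, [("sliver", box(0, 0, 1.0, 1.0))])
        assert np.isnan(out["sliver"])


# -- component assembly ---------------------------------------------------

def _toy_bundle(transit_scale=1.0):
    """Tiny 8x8 world with fully known layers."""
    n, cell = 8, 25.0
    template = GridLayer((0, 0), cell, np.zeros((n, n)))
    rng = np.random.default_rng(21)
    pop = template.like(rng.poisson(3.0, (n, n)).astype(float), "count")
    codes = rng.integers(0, 6, (n, n))
    landuse = template.like(codes, "category")
    sidewalk = template.like(rng.uniform(0, 1, (n, n)), "fraction")
    roads = [(LineString([(100, 0), (100, 200)]), "street"),
             (LineString([(0, 100), (100, 100)]), "street"),
             (LineString([(100, 100), (200, 100)]), "street")]
    # note: vertical line is unbroken at (100,100) -> endpoints only
    transit = rng.uniform(0, 200, (int(6 * transit_scale), 2))
    centroids = pd.DataFrame({"unit_id": ["A", "B", "C"],
                              "x": [30.0, 110.0, 180.0],
                              "y": [30.0, 110.0, 60.0]})
    zones = [("west", box(0, 0, 100, 200)), ("east", box(100, 0, 200, 200))]
    return LandscapeBundle(population=pop, landuse=landuse, sidewalk=sidewalk,
                           roads=roads, transit_points=transit,
                           centroids=centroids, neighbourhoods=zones)


class TestComputeComponents:
    def test_uniform_landscape_gives_identical_vectors(self):
        b = _toy_bundle()
        b.population.values[:] = 2.0
        b.landuse.values[:] = 3          # all residential
        b.sidewalk.values[:] = 0.4
        b.transit_points = np.empty((0, 2))
        b.roads = []
        out = compute_components(b, 1000.0)   # buffer covers whole extent
        for c in COMPONENTS:
            assert out[c].nunique() == 1

    def test_doubling_transit_only_scales_transit(self):
        rng = np.random.default_rng(2)
        b1 = _toy_bundle()
        b2 = _toy_bundle()
        b2.transit_points = np.vstack([b1.transit_points, b1.transit_points])
        o1 = compute_components(b1, 150.0)
        o2 = compute_components(b2, 150.0)
        np.testing.assert_allclose(o2["public_transport_density"],
                                   2 * o1["public_transport_density"], rtol=1e-12)
        for c in COMPONENTS:
            if c != "public_transport_density":
                np.testing.assert_array_equal(o1[c], o2[c])

    def test_toy_world_matches_hand_computation(self):
        """Unit A of the toy world, 150 m buffer, checked by direct arithmetic."""
        b = _toy_bundle()
        out = compute_components(b, 150.0).set_index("unit_id")
        # unit A sits in cell (1, 1); enumerate the in-bounds kernel cells
        offsets = [(dy, dx) for dy in range(-6, 7) for dx in range(-6, 7)
                   if (dx * dx + dy * dy) * 625 <= 150 ** 2]
        cells = [(1 + dy, 1 + dx) for dy, dx in offsets
                 if 0 <= 1 + dy < 8 and 0 <= 1 + dx < 8]
        popmean = np.mean([b.population.values[c] for c in cells])
        assert out.loc["A", "population_density"] == pytest.approx(
            popmean / 625 * 1e4, rel=1e-9)          # per-cell -> per hectare
        codes = np.array([b.landuse.values[c] for c in cells])
        retail = np.mean((codes == 1) | (codes == 2))
        assert out.loc["A", "retail_service_density"] == pytest.approx(retail, rel=1e-9)
        shares = np.array([(codes == k).mean() for k in range(1, 6)])
        shares = shares / shares.sum()
        ent = -sum(p * np.log(p) for p in shares if p > 0) / np.log(5)
        assert out.loc["A", "land_use_mix"] == pytest.approx(ent, rel=1e-9)
        swmean = np.mean([b.sidewalk.values[c] for c in cells])
        assert out.loc["A", "sidewalk_density"] == pytest.approx(swmean, rel=1e-9)

    def test_missing_layer_raises_with_name(self):
        b = _toy_bundle()
        b.sidewalk = None
        with pytest.raises(ValueError, match="sidewalk"):
            compute_components(b, 150.0)

    def test_toy_street_network_has_one_true_intersection(self):
        b = _toy_bundle()
        pts = extract_true_intersections(b.roads)
        # the vertical line passes through (100,100) unbroken: only the two
        # horizontal segment ends meet an interior point of it -> degree 2;
        # the shared endpoint of the two horizontals at (100,100) has degree 2
        assert len(pts) == 0
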