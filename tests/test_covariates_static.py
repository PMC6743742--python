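"""Pixel area, slope, land cover, distances, climate, roads, intersections."""

import math

import numpy as np
import pytest
import shapely

from popgrid.covariates_static import (DEFAULT_LANDCOVER_MAPPING, EarthModel,
                                       PriorityLine, binary_extract,
                                       climate_annual, detect_intersections,
                                       distance_to_feature, haversine_m,
                                       mapping_from_csv, mapping_to_csv,
                                       pixel_area_grid, priority_rasterize,
                                       reclassify_landcover,
                                       restore_offshore_links,
                                       slope_from_dem, union_binary)
from popgrid.grid import GridRaster, define_mastergrid
from .conftest import make_raster

EARTH = EarthModel()


class TestPixelArea:
    def test_rows_have_constant_area(self):
        g = define_mastergrid((0, 0, 10, 10), 0.5)
        area = pixel_area_grid(g, EARTH)
        assert (np.ptp(area.values, axis=1) == 0).all()

    def test_global_quarter_cells(self):
        # 2x2 global grid of 90-degree cells: each hemisphere band has area
        # 2*pi*R^2, split across two cells
        g = define_mastergrid((-180, -90, 180, 90), 90.0)
        area = pixel_area_grid(g, EARTH)
        np.testing.assert_allclose(area.values, (math.pi / 2) * EARTH.R ** 2,
                                   rtol=1e-12)

    @pytest.mark.parametrize("cell", [90.0, 10.0, 1.0])
    def test_global_sum_is_sphere_area(self, cell):
        g = define_mastergrid((-180, -90, 180, 90), cell)
        total = pixel_area_grid(g, EARTH).values.sum()
        assert total == pytest.approx(4 * math.pi * EARTH.R ** 2, rel=1e-9)

    def test_row_area_decreases_with_latitude(self):
        # one hemisphere: row-centre |latitudes| are all distinct
        g = define_mastergrid((0, 0, 180, 90), 10.0)
        rows = pixel_area_grid(g, EARTH).values[:, 0]
        lat_abs = np.abs(g.lat_centers())
        order = np.argsort(lat_abs)
        assert (np.diff(rows[order]) < 0).all()
        # and symmetric rows north/south of the equator match exactly
        gs = define_mastergrid((0, -90, 180, 90), 10.0)
        sym = pixel_area_grid(gs, EARTH).values[:, 0]
        np.testing.assert_allclose(sym, sym[::-1], rtol=1e-12)


class TestSlope:
    def test_constant_dem_zero_slope(self):
        g = define_mastergrid((0, 0, 1, 1), 0.1)
        out = slope_from_dem(make_raster(g, np.full(g.shape, 500.0)), EARTH)
        interior = out.values[1:-1, 1:-1]
        assert (interior == 0).all()
        assert (out.values[0, :] == out.nodata).all()

    def test_plane_rising_eastward_at_equator(self):
        # 1 m per 100 m eastward -> arctan(0.01) = 0.5729 degrees
        g = define_mastergrid((0, -0.05, 0.5, 0.05), 0.01)
        dx = EARTH.R * math.radians(0.01)   # ~1113 m at the equator
        cols = np.arange(g.n_cols) * dx * 0.01
        dem = np.tile(cols, (g.n_rows, 1))
        out = slope_from_dem(make_raster(g, dem), EARTH)
        mid = out.values[g.n_rows // 2, g.n_cols // 2]
        assert mid == pytest.approx(math.degrees(math.atan(0.01)), rel=1e-3)

    def test_nodata_contaminates_neighbourhood(self):
        g = define_mastergrid((0, 0, 1, 1), 0.1)
        v = np.full(g.shape, 100.0)
        v[5, 5] = -99999.0
        out = slope_from_dem(make_raster(g, v), EARTH)
        assert (out.values[4:7, 4:7] == out.nodata).all()
        assert out.values[3, 3] == 0.0

    def test_too_small_raster_rejected(self):
        g = define_mastergrid((0, 0, 0.5, 0.5), 0.25)
        with pytest.raises(ValueError):
            slope_from_dem(make_raster(g, np.zeros(g.shape)), EARTH)


class TestReclassifyLandcover:
    def test_default_mapping_yields_nine_classes(self, grid4):
        codes = sorted(DEFAULT_LANDCOVER_MAPPING)
        vals = np.resize(codes, grid4.shape[0] * grid4.shape[1]).reshape(grid4.shape)
        out = reclassify_landcover(make_raster(grid4, vals, "categorical"))
        assert set(DEFAULT_LANDCOVER_MAPPING.values()) == set(range(1, 10))
        assert set(np.unique(out.values)) <= set(range(1, 10))

    def test_identity_mapping_is_identity(self, grid4):
        vals = np.arange(16).reshape(4, 4) + 1
        out = reclassify_landcover(make_raster(grid4, vals, "categorical"),
                                   {i: i for i in range(1, 17)})
        np.testing.assert_array_equal(out.values, vals)

    def test_histogram_conservation(self, grid4):
        rng = np.random.default_rng(1)
        codes = [10, 50, 190, 210]
        vals = rng.choice(codes, size=grid4.shape)
        out = reclassify_landcover(make_raster(grid4, vals, "categorical"))
        for agg in set(DEFAULT_LANDCOVER_MAPPING[c] for c in codes):
            srcs = [c for c in codes if DEFAULT_LANDCOVER_MAPPING[c] == agg]
            assert (out.values == agg).sum() == sum(
                (vals == c).sum() for c in srcs)

    def test_unmapped_code_rejected_with_listing(self, grid4):
        vals = np.full(grid4.shape, 777)
        with pytest.raises(ValueError, match="777"):
            reclassify_landcover(make_raster(grid4, vals, "categorical"))

    def test_mapping_csv_round_trip(self, tmp_path):
        path = tmp_path / "mapping.csv"
        mapping_to_csv(DEFAULT_LANDCOVER_MAPPING, path)
        assert mapping_from_csv(path) == DEFAULT_LANDCOVER_MAPPING


class TestBinaryExtract:
    def test_all_observed_classes_gives_ones(self, grid4):
        vals = np.arange(16).reshape(4, 4)
        out = binary_extract(make_raster(grid4, vals, "categorical"),
                             classes=range(16))
        assert (out.values == 1).all()

    def test_empty_intersection_gives_zeros(self, grid4):
        vals = np.ones(grid4.shape, int)
        out = binary_extract(make_raster(grid4, vals, "categorical"), [9])
        assert (out.values == 0).all()

    def test_membership_oracle_and_presence_mode(self, grid4):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 5, grid4.shape)
        src = make_raster(grid4, vals, "categorical")
        binary = binary_extract(src, [1, 3], "binary")
        presence = binary_extract(src, [1, 3], "presence")
        for r in range(4):
            for c in range(4):
                member = vals[r, c] in (1, 3)
                assert binary.values[r, c] == (1 if member else 0)
                assert presence.values[r, c] == (1 if member else src.nodata)

    def test_reclass_then_extract_commutes_with_source_membership(self, grid4):
        rng = np.random.default_rng(9)
        codes = [10, 50, 190, 210, 220]
        vals = rng.choice(codes, size=grid4.shape)
        src = make_raster(grid4, vals, "categorical")
        agg = 7  # built
        via_reclass = binary_extract(reclassify_landcover(src), [agg])
        srcs = [c for c in codes if DEFAULT_LANDCOVER_MAPPING[c] == agg]
        direct = binary_extract(src, srcs)
        np.testing.assert_array_equal(via_reclass.values, direct.values)


class TestDistanceToFeature:
    def test_feature_cells_are_zero(self, grid4):
        f = np.zeros(grid4.shape, int)
        f[2, 2] = 1
        out = distance_to_feature(make_raster(grid4, f, "binary", 255), EARTH)
        assert out.values[2, 2] == 0.0

    def test_matches_exhaustive_haversine_oracle(self):
        g = define_mastergrid((0, 0, 0.9, 0.9), 0.1)
        f = np.zeros(g.shape, int)
        f[1, 6] = 1
        f[7, 2] = 1
        out = distance_to_feature(make_raster(g, f, "binary", 255), EARTH)
        lon, lat = g.center_mesh()
        feats = np.argwhere(f == 1)
        for r in range(g.n_rows):
            for c in range(g.n_cols):
                d = min(haversine_m(lon[r, c], lat[r, c],
                                    lon[fr, fc], lat[fr, fc], EARTH.R)
                        for fr, fc in feats)
                assert out.values[r, c] == pytest.approx(d, rel=1e-9, abs=1e-6)

    def test_monotone_towards_feature_along_row(self):
        g = define_mastergrid((0, 0, 1, 1), 0.1)
        f = np.zeros(g.shape, int)
        f[5, 0] = 1
        out = distance_to_feature(make_raster(g, f, "binary", 255), EARTH)
        assert (np.diff(out.values[5, :]) > 0).all()

    def test_no_features_rejected(self, grid4):
        with pytest.raises(ValueError):
            distance_to_feature(make_raster(grid4, np.zeros(grid4.shape, int),
                                            "binary", 255), EARTH)


class TestClimateAnnual:
    def test_constant_months(self, grid4):
        months = [make_raster(grid4, np.full(grid4.shape, 4.0)) for _ in range(12)]
        assert (climate_annual(months, "mean").values == 4.0).all()
        assert (climate_annual(months, "sum").values == 48.0).all()

    def test_sequence_mean_and_sum(self, grid4):
        months = [make_raster(grid4, np.full(grid4.shape, float(m)))
                  for m in range(1, 13)]
        assert (climate_annual(months, "mean").values == 6.5).all()
        assert (climate_annual(months, "sum").values == 78.0).all()

    def test_any_month_nodata_propagates(self, grid4):
        months = [make_raster(grid4, np.full(grid4.shape, 1.0)) for _ in range(12)]
        v = months[4].values.copy()
        v[1, 1] = months[4].nodata
        months[4] = make_raster(grid4, v)
        for stat in ("mean", "sum"):
            out = climate_annual(months, stat)
            assert out.values[1, 1] == out.nodata
            assert out.values[0, 0] != out.nodata

    def test_wrong_month_count_rejected(self, grid4):
        months = [make_raster(grid4, np.zeros(grid4.shape))] * 11
        with pytest.raises(ValueError):
            climate_annual(months, "mean")


class TestPriorityRasterize:
    def test_max_priority_wins_in_shared_cell(self, grid4):
        # both lines cross cell (1,1) (x in [0.25,0.5), y in (0.5,0.75])
        l10 = PriorityLine(shapely.LineString([(0.26, 0.6), (0.45, 0.7)]), 10)
        l14 = PriorityLine(shapely.LineString([(0.3, 0.55), (0.4, 0.72)]), 14)
        out = priority_rasterize([l10, l14], grid4)
        assert out.values[1, 1] == 14

    def test_low_classes_dropped_by_default_retention(self, grid4):
        minor = PriorityLine(shapely.LineString([(0.1, 0.1), (0.9, 0.9)]), 5)
        out = priority_rasterize([minor], grid4)
        assert (out.values == 0).all()

    def test_empty_line_set_all_zero(self, grid4):
        assert (priority_rasterize([], grid4).values == 0).all()

    def test_matches_bruteforce_segment_cell_oracle(self):
        g = define_mastergrid((0, 0, 1, 1), 0.125)
        rng = np.random.default_rng(4)
        lines = [PriorityLine(shapely.LineString(rng.uniform(0, 1, (3, 2))),
                              int(p)) for p in (9, 12, 17)]
        out = priority_rasterize(lines, g)
        s = g.cell_size
        for r in range(g.n_rows):
            for c in range(g.n_cols):
                cell = shapely.box(g.origin_lon + c * s,
                                   g.origin_lat - (r + 1) * s,
                                   g.origin_lon + (c + 1) * s,
                                   g.origin_lat - r * s)
                expect = max((ln.priority for ln in lines
                              if ln.geometry.intersects(cell)), default=0)
                assert out.values[r, c] == expect


class TestRestoreOffshoreLinks:
    def make(self, grid4):
        highways = make_raster(grid4, np.zeros(grid4.shape, int), "categorical", -1)
        links = np.zeros(grid4.shape, int)
        links[0, 0] = 30   # offshore
        links[3, 3] = 30   # on land
        land = np.ones(grid4.shape, int)
        land[0, 0] = 0
        return (highways, make_raster(grid4, links, "categorical", -1),
                make_raster(grid4, land, "binary", 255))

    def test_offshore_link_written_with_value_30(self, grid4):
        out = restore_offshore_links(*self.make(grid4))
        assert out.values[0, 0] == 30

    def test_on_land_link_discarded(self, grid4):
        out = restore_offshore_links(*self.make(grid4))
        assert out.values[3, 3] == 0

    def test_no_links_is_identity(self, grid4):
        highways, _, land = self.make(grid4)
        empty = make_raster(grid4, np.zeros(grid4.shape, int), "categorical", -1)
        out = restore_offshore_links(highways, empty, land)
        np.testing.assert_array_equal(out.values, highways.values)


class TestDetectIntersections:
    def test_continuing_highway_has_no_intersection(self):
        a = PriorityLine(shapely.LineString([(0, 0), (1, 0)]), 10, name="A1")
        b = PriorityLine(shapely.LineString([(1, 0), (2, 0)]), 10, name="A1")
        assert detect_intersections([a, b]) == []

    def test_crossing_different_names_gives_one_point(self):
        a = PriorityLine(shapely.LineString([(0, 0), (2, 2)]), 10, name="A")
        b = PriorityLine(shapely.LineString([(0, 2), (2, 0)]), 10, name="B")
        pts = detect_intersections([a, b])
        assert len(pts) == 1
        assert (pts[0].x, pts[0].y) == (1.0, 1.0)

    def test_bridge_crossing_suppressed(self):
        a = PriorityLine(shapely.LineString([(0, 0), (2, 2)]), 10, name="A")
        bridge = PriorityLine(shapely.LineString([(0, 2), (2, 0)]), 30,
                              name="B", link_flag=True)
        assert detect_intersections([a, bridge]) == []

    def test_same_geometry_different_priority_intersects(self):
        a = PriorityLine(shapely.LineString([(0, 0), (1, 0)]), 10, name="A")
        b = PriorityLine(shapely.LineString([(1, 0), (1, 1)]), 12, name="A")
        pts = detect_intersections([a, b])
        assert len(pts) == 1 and (pts[0].x, pts[0].y) == (1.0, 0.0)

    def test_symmetric_in_input_order(self):
        a = PriorityLine(shapely.LineString([(0, 0), (2, 2)]), 9, name="A")
        b = PriorityLine(shapely.LineString([(0, 2), (2, 0)]), 11, name="B")
        p1 = detect_intersections([a, b])
        p2 = detect_intersections([b, a])
        assert [(p.x, p.y) for p in p1] == [(p.x, p.y) for p in p2]

    def test_invariant_to_vertex_densification(self):
        a = PriorityLine(shapely.LineString([(0, 0), (2, 2)]), 9, name="A")
        a_dense = PriorityLine(
            shapely.segmentize(shapely.LineString([(0, 0), (2, 2)]), 0.1),
            9, name="A")
        b = PriorityLine(shapely.LineString([(0, 2), (2, 0)]), 11, name="B")
        p1 = detect_intersections([a, b])
        p2 = detect_intersections([a_dense, b])
        assert [(p.x, p.y) for p in p1] == [(p.x, p.y) for p in p2]


def test_union_binary_priority_mosaic(grid4):
    water = np.zeros(grid4.shape, int); water[0] = 1
    banks = np.zeros(grid4.shape, int); banks[1] = 1
    ways = np.zeros(grid4.shape, int); ways[2] = 1
    out = union_binary([make_raster(grid4, m, "binary", 255)
                        for m in (water, banks, ways)])
    assert (out.values[:3] == 1).all() and (out.values[3] == 0).all()
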