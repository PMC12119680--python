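"""Friction-surface and least-cost-path tests, including exact equivalence
with an independent shortest-path oracle."""

import numpy as np
import networkx as nx
import pytest
import shapely

from anaemia_access.accessibility import (
    AccessibilityError,
    FrictionSurface,
    SpeedTable,
    bin_travel_time,
    build_friction_surface,
    least_cost_travel_time,
    zonal_mean_travel_time,
)
from anaemia_access.raster import RasterGrid
from anaemia_access.region import EnumerationArea, LandscapeLayers

from conftest import make_uniform_friction_layers


def uniform_friction(n, f, pixel_size=12.5, impassable=None):
    imp = np.zeros((n, n), dtype=bool) if impassable is None else impassable
    data = np.where(imp, np.nan, f)
    return FrictionSurface(RasterGrid(data, pixel_size), imp)


def oracle_travel_seconds(friction: FrictionSurface, origin):
    """Independent Dijkstra on an explicitly built networkx graph."""
    f = friction.grid.data
    px = friction.pixel_size
    nrow, ncol = f.shape
    G = nx.Graph()
    for r in range(nrow):
        for c in range(ncol):
            if friction.impassable[r, c]:
                continue
            G.add_node((r, c))
            for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and not friction.impassable[rr, cc]:
                    d = px * (np.sqrt(2.0) if dr and dc else 1.0)
                    G.add_edge((r, c), (rr, cc), weight=d * (f[r, c] + f[rr, cc]) / 2)
    lengths = nx.single_source_dijkstra_path_length(G, origin, weight="weight")
    out = np.full(f.shape, np.nan)
    for (r, c), v in lengths.items():
        out[r, c] = v
    return out


# ---------------------------------------------------------------------------
# friction surface
# ---------------------------------------------------------------------------


class TestFriction:
    def test_unit_conversion_tarmac(self):
        assert SpeedTable.default().entries["tarmac"].friction_s_per_m == pytest.approx(
            0.045
        )

    def test_water_impassable(self):
        layers = make_uniform_friction_layers(5)
        layers.barrier_mask.data[0, 0] = True
        fr = build_friction_surface(layers, SpeedTable.default())
        assert fr.impassable[0, 0]
        assert np.isnan(fr.grid.data[0, 0])

    def test_road_overrides_land_cover(self):
        # gravel road (40 km/h) over bushland (walk 4 km/h) -> 0.09 s/m
        layers = make_uniform_friction_layers(5, cover_code=4)
        layers.road_class.data[1, 1] = 2
        fr = build_friction_surface(layers, SpeedTable.default())
        assert fr.grid.data[1, 1] == pytest.approx(0.09)
        assert fr.grid.data[0, 0] == pytest.approx(3.6 / 4.0)

    def test_unmapped_class_raises_with_name(self):
        layers = make_uniform_friction_layers(5, cover_code=4)
        speeds = SpeedTable(entries={"tarmac": SpeedTable.default().entries["tarmac"]})
        with pytest.raises(AccessibilityError, match="bushland"):
            build_friction_surface(layers, speeds)


# ---------------------------------------------------------------------------
# least-cost travel time
# ---------------------------------------------------------------------------


class TestLeastCost:
    def test_uniform_rook_path(self):
        # walk 5 km/h = 0.72 s/m, 12.5 m pixels, 4 rook steps -> 36 s = 0.6 min
        fr = uniform_friction(9, 0.72)
        tt = least_cost_travel_time(fr, (4, 4))
        assert tt.grid.data[4, 8] == pytest.approx(0.6)
        assert tt.grid.data[4, 4] == 0.0

    def test_uniform_diagonal_step(self):
        fr = uniform_friction(3, 0.72)
        tt = least_cost_travel_time(fr, (0, 0))
        assert tt.grid.data[1, 1] * 60 == pytest.approx(12.5 * np.sqrt(2) * 0.72)

    def test_wall_detour_matches_oracle(self):
        imp = np.zeros((5, 5), dtype=bool)
        imp[0:4, 2] = True  # wall with a gap at the bottom
        fr = uniform_friction(5, 0.5, impassable=imp)
        tt = least_cost_travel_time(fr, (0, 0))
        oracle = oracle_travel_seconds(fr, (0, 0))
        np.testing.assert_allclose(
            tt.grid.data * 60, oracle, rtol=1e-12, equal_nan=True
        )
        # the detour is strictly longer than the unobstructed straight line
        assert tt.grid.data[0, 4] * 60 > 4 * 12.5 * 0.5

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.05, 1.0, size=(6, 6))
        imp = rng.random((6, 6)) < 0.2
        imp[0, 0] = False
        fr = FrictionSurface(RasterGrid(np.where(imp, np.nan, f), 12.5), imp)
        tt = least_cost_travel_time(fr, (0, 0))
        oracle = oracle_travel_seconds(fr, (0, 0))
        np.testing.assert_allclose(tt.grid.data * 60, oracle, rtol=1e-10, equal_nan=True)

    def test_monotone_under_friction_increase(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 1.0, size=(8, 8))
        fr = uniform_friction(8, 0.0)
        fr.grid.data[:] = f
        base = least_cost_travel_time(fr, (0, 0)).grid.data
        for _ in range(10):
            r, c = rng.integers(0, 8, 2)
            f2 = f.copy()
            f2[r, c] *= rng.uniform(1.5, 4.0)
            fr2 = FrictionSurface(RasterGrid(f2, 12.5), np.zeros((8, 8), bool))
            bumped = least_cost_travel_time(fr2, (0, 0)).grid.data
            assert np.all(bumped >= base - 1e-12)

    def test_triangle_consistency(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(0.1, 1.0, size=(7, 7))
        fr = FrictionSurface(RasterGrid(f, 12.5), np.zeros((7, 7), bool))
        t = least_cost_travel_time(fr, (3, 3)).grid.data * 60
        for r in range(7):
            for c in range(7):
                for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 7 and 0 <= cc < 7:
                        d = 12.5 * (np.sqrt(2) if dr and dc else 1.0)
                        edge = d * (f[r, c] + f[rr, cc]) / 2
                        assert abs(t[r, c] - t[rr, cc]) <= edge + 1e-9

    def test_uniform_surface_closed_form(self):
        f, px = 0.3, 12.5
        fr = uniform_friction(9, f, pixel_size=px)
        t = least_cost_travel_time(fr, (0, 0)).grid.data * 60
        for i in range(9):
            for j in range(9):
                expected = f * px * (np.sqrt(2) * min(i, j) + abs(i - j))
                assert t[i, j] == pytest.approx(expected)

    def test_impassable_origin_raises(self):
        imp = np.zeros((4, 4), bool)
        imp[0, 0] = True
        fr = uniform_friction(4, 0.5, impassable=imp)
        with pytest.raises(AccessibilityError):
            least_cost_travel_time(fr, (0, 0))

    def test_unreachable_pixels_flagged_not_error(self):
        imp = np.zeros((5, 5), bool)
        imp[:, 2] = True  # full wall
        fr = uniform_friction(5, 0.5, impassable=imp)
        tt = least_cost_travel_time(fr, (0, 0))
        assert np.isnan(tt.grid.data[0, 4])
        assert not tt.reachable[0, 4]
        assert tt.reachable[4, 0]


# ---------------------------------------------------------------------------
# zonal means and binning
# ---------------------------------------------------------------------------


def _ea(ea_id, poly):
    return EnumerationArea(
        ea_id=ea_id, polygon=poly, centroid=(poly.centroid.x, poly.centroid.y),
        pop_u5=10, ntl=0.0, pfpr=0.3,
    )


class TestZonal:
    def test_two_pixel_mean(self):
        data = np.array([[10.0, 20.0]])
        tt_grid = RasterGrid(data, 10.0)
        tt = type("TT", (), {})()
        from anaemia_access.accessibility import TravelTimeRaster

        tt = TravelTimeRaster(tt_grid, np.ones((1, 2), bool), (0, 0))
        ea = _ea("A", shapely.box(0, 0, 20, 10))
        out = zonal_mean_travel_time(tt, [ea])
        assert out.loc[0, "mean_travel_min"] == pytest.approx(15.0)
        assert ea.mean_travel_min == pytest.approx(15.0)

    def test_hospital_only_ea_is_zero(self):
        from anaemia_access.accessibility import TravelTimeRaster

        data = np.array([[0.0, 7.0]])
        tt = TravelTimeRaster(RasterGrid(data, 10.0), np.ones((1, 2), bool), (0, 0))
        ea = _ea("H", shapely.box(0, 0, 10, 10))
        out = zonal_mean_travel_time(tt, [ea])
        assert out.loc[0, "mean_travel_min"] == 0.0

    def test_barrier_straddling_mean_over_reachable(self):
        from anaemia_access.accessibility import TravelTimeRaster

        # 3 pixels: 12, unreachable, 18 -> mean 15
        data = np.array([[12.0, np.nan, 18.0]])
        reach = np.array([[True, False, True]])
        tt = TravelTimeRaster(RasterGrid(data, 10.0), reach, (0, 0))
        ea = _ea("B", shapely.box(0, 0, 30, 10))
        out = zonal_mean_travel_time(tt, [ea])
        assert out.loc[0, "mean_travel_min"] == pytest.approx(15.0)

    def test_unreachable_ea_flagged_with_warning(self):
        from anaemia_access.accessibility import TravelTimeRaster

        data = np.array([[np.nan, 5.0]])
        reach = np.array([[False, True]])
        tt = TravelTimeRaster(RasterGrid(data, 10.0), reach, (0, 1))
        ea = _ea("X", shapely.box(0, 0, 10, 10))
        with pytest.warns(UserWarning, match="no reachable pixel"):
            out = zonal_mean_travel_time(tt, [ea])
        assert np.isnan(out.loc[0, "mean_travel_min"])


class TestBinning:
    @pytest.mark.parametrize(
        "minutes,expected",
        [
            (29.99, "<30"),
            (30.0, "30-59"),
            (36.0, "30-59"),  # the published severe-anaemia median falls here
            (59.999, "30-59"),
            (60.0, "60-89"),
            (90.0, ">=90"),
            (0.0, "<30"),
        ],
    )
    def test_30min_classes(self, minutes, expected):
        assert bin_travel_time(minutes) == expected

    @pytest.mark.parametrize(
        "minutes,expected", [(14.9, "<15"), (15.0, "15-29"), (89.9, "75-89"), (95, ">=90")]
    )
    def test_15min_bands(self, minutes, expected):
        assert bin_travel_time(minutes, scheme="15min") == expected

    def test_negative_rejected(self):
        with pytest.raises(AccessibilityError):
            bin_travel_time(-1.0)
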