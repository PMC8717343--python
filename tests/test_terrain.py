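"""Terrain derivatives: closed forms, counts, invariances."""

import numpy as np
import pytest

from bathysdm import terrain as T
from bathysdm.grids import GridSurface

from conftest import desk_scenario
from bathysdm.synth import generate_seafloor


def _grid_from_elevation(fn, n=9, cell=1.0):
    """Depth grid whose elevation (-depth) follows fn(x, y) at cell centres."""
    g = GridSurface(0.0, n * cell, cell, np.zeros((n, n)))
    gx, gy = g.centre_mesh()
    return g.copy_with(-fn(gx, gy))


class TestGaussianSmooth:
    def test_constant_surface_unchanged(self):
        g = GridSurface(0, 8, 1.0, np.full((8, 8), 3.0))
        np.testing.assert_allclose(T.gaussian_smooth(g).values, 3.0, atol=1e-12)

    def test_linear_ramp_preserved_in_interior(self):
        g = _grid_from_elevation(lambda x, y: x + 2 * y)
        sm = T.gaussian_smooth(g)
        np.testing.assert_allclose(sm.values[2:-2, 2:-2], g.values[2:-2, 2:-2],
                                   atol=1e-9)

    def test_impulse_response_equals_kernel_centre_weight(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 1.0
        sm = T.gaussian_smooth(GridSurface(0, 9, 1.0, vals))
        ax = np.arange(5) - 2.0
        k1 = np.exp(-0.5 * ax ** 2)
        kernel = np.outer(k1, k1) / np.outer(k1, k1).sum()
        assert sm.values[4, 4] == pytest.approx(kernel[2, 2])

    def test_small_grids_rejected(self):
        with pytest.raises(ValueError):
            T.gaussian_smooth(GridSurface(0, 4, 1.0, np.zeros((4, 4))))


class TestResampleBilinear:
    def test_identity_cell_size_preserves_values(self):
        g = _grid_from_elevation(lambda x, y: np.sin(x) + y, n=12, cell=3.0)
        out = T.resample_bilinear(g, 3.0)
        np.testing.assert_allclose(out.values, g.values, atol=1e-12)

    def test_constant_stays_constant(self):
        g = GridSurface(0, 36, 3.0, np.full((12, 12), 5.0))
        np.testing.assert_allclose(T.resample_bilinear(g, 9.0).values, 5.0)

    def test_plane_reproduced_when_coarsening(self):
        g = _grid_from_elevation(lambda x, y: x + 2 * y, n=12, cell=3.0)
        out = T.resample_bilinear(g, 9.0)
        gx, gy = out.centre_mesh()
        np.testing.assert_allclose(out.values, -(gx + 2 * gy), atol=1e-9)


class TestHornSlopeAspect:
    def test_flat_seafloor_has_zero_slope_and_components(self):
        g = GridSurface(0, 9, 1.0, np.full((9, 9), 40.0))
        slope, ns, we = T.horn_slope_aspect(g)
        np.testing.assert_allclose(slope.values[1:-1, 1:-1], 0.0)
        np.testing.assert_allclose(ns.values[1:-1, 1:-1], 0.0)
        np.testing.assert_allclose(we.values[1:-1, 1:-1], 0.0)

    def test_east_rising_plane_slopes_west(self):
        # elevation gradient 2 east: slope atan(2) ~ 63.435 deg, aspect 270
        g = _grid_from_elevation(lambda x, y: 2 * x)
        slope, ns, we = T.horn_slope_aspect(g)
        assert slope.values[4, 4] == pytest.approx(np.degrees(np.arctan(2)))
        assert ns.values[4, 4] == pytest.approx(0.0, abs=1e-12)
        assert we.values[4, 4] == pytest.approx(-1.0)

    def test_north_rising_plane_slopes_south(self):
        g = _grid_from_elevation(lambda x, y: y)
        slope, ns, we = T.horn_slope_aspect(g)
        assert slope.values[4, 4] == pytest.approx(45.0)
        assert ns.values[4, 4] == pytest.approx(-1.0)
        assert we.values[4, 4] == pytest.approx(0.0, abs=1e-12)

    def test_aspect_components_lie_on_unit_circle_where_sloped(self):
        dem = generate_seafloor(desk_scenario(30))
        slope, ns, we = T.horn_slope_aspect(dem)
        sl = slope.values[1:-1, 1:-1]
        norm = ns.values[1:-1, 1:-1] ** 2 + we.values[1:-1, 1:-1] ** 2
        np.testing.assert_allclose(norm[sl > 0], 1.0, atol=1e-9)
        assert np.nanmax(np.abs(ns.values[1:-1, 1:-1])) <= 1.0 + 1e-12


class TestFocalStats:
    def test_impulse_window_values(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 1.0
        g = GridSurface(0, 5, 1.0, vals)
        assert T.focal_stat(g, "TRI").values[2, 2] == pytest.approx(1.0)
        assert T.focal_stat(g, "TPI").values[2, 2] == pytest.approx(1.0)
        assert T.focal_stat(g, "roughness").values[2, 2] == pytest.approx(1.0)
        assert T.focal_stat(g, "SD").values[2, 2] == pytest.approx(np.std(
            [1.0] + [0.0] * 8, ddof=1))

    def test_any_plane_has_zero_tpi(self):
        g = _grid_from_elevation(lambda x, y: 3 * x - 2 * y + 1)
        np.testing.assert_allclose(T.focal_stat(g, "TPI").values[1:-1, 1:-1],
                                   0.0, atol=1e-10)

    def test_constant_window_metrics_all_zero(self):
        g = GridSurface(0, 5, 1.0, np.full((5, 5), 9.0))
        for metric in ("SD", "TRI", "roughness"):
            np.testing.assert_allclose(T.focal_stat(g, metric).values[1:-1, 1:-1],
                                       0.0, atol=1e-12)

    def test_unknown_metric_rejected(self):
        g = GridSurface(0, 5, 1.0, np.zeros((5, 5)))
        with pytest.raises(ValueError):
            T.focal_stat(g, "VRM")


class TestMeanCurvature:
    def test_plane_has_zero_curvature(self):
        g = _grid_from_elevation(lambda x, y: 4 * x - y + 2)
        np.testing.assert_allclose(T.mean_curvature(g).values[1:-1, 1:-1],
                                   0.0, atol=1e-10)

    def test_elevation_bowl_is_concave_negative(self):
        g = _grid_from_elevation(lambda x, y: (x - 4.5) ** 2 + (y - 4.5) ** 2)
        assert T.mean_curvature(g).values[4, 4] == pytest.approx(-2.0)

    def test_elevation_dome_is_convex_positive(self):
        g = _grid_from_elevation(lambda x, y: -((x - 4.5) ** 2 + (y - 4.5) ** 2))
        assert T.mean_curvature(g).values[4, 4] == pytest.approx(2.0)


class TestBuildStack:
    def test_single_resolution_yields_nine_layers(self):
        dem = GridSurface(0, 200, 10.0, np.random.default_rng(0).uniform(
            20, 30, (20, 20)))
        stack = T.build_stack(dem, [10.0])
        assert len(stack.layers) == 9

    def test_four_resolutions_yield_thirty_three_layers(self):
        dem = GridSurface(0, 1000, 10.0, np.random.default_rng(1).uniform(
            20, 30, (100, 100)))
        stack = T.build_stack(dem, [10.0, 30.0, 50.0, 80.0])
        assert len(stack.layers) == 33
        assert len(stack.feature_names) == 33

    def test_flat_dem_gives_zero_derivatives_everywhere(self):
        dem = GridSurface(0, 300, 10.0, np.full((30, 30), 55.0))
        stack = T.build_stack(dem, [10.0, 30.0])
        for name, layer in stack.layers.items():
            if name.startswith("depth"):
                continue
            vals = layer.values[~layer.nodata_mask]
            np.testing.assert_allclose(vals, 0.0, atol=1e-9, err_msg=name)

    def test_sub_native_resolution_rejected(self):
        dem = GridSurface(0, 200, 10.0, np.zeros((20, 20)))
        with pytest.raises(ValueError, match="finer than the native cell"):
            T.build_stack(dem, [5.0])

    def test_depth_translation_moves_only_the_depth_layer(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(20, 30, (30, 30))
        a = T.build_stack(GridSurface(0, 300, 10.0, vals), [10.0])
        b = T.build_stack(GridSurface(0, 300, 10.0, vals + 100.0), [10.0])
        for name in a.layers:
            va, vb = a.layers[name].values, b.layers[name].values
            ok = ~np.isnan(va)
            if name.startswith("depth"):
                np.testing.assert_allclose(vb[ok] - va[ok], 100.0, atol=1e-9)
            else:
                np.testing.assert_allclose(vb[ok], va[ok], atol=1e-9, err_msg=name)

    def test_written_stack_round_trips(self, tmp_path):
        dem = GridSurface(0, 200, 10.0, np.random.default_rng(3).uniform(
            20, 30, (20, 20)))
        stack = T.build_stack(dem, [10.0])
        stack.write(tmp_path / "stack")
        assert (tmp_path / "stack" / "manifest.json").exists()
        reread = GridSurface.from_ascii(tmp_path / "stack" / "slope_10.asc")
        orig = stack.layers["slope_10"]
        np.testing.assert_allclose(reread.values[~reread.nodata_mask],
                                   orig.values[~orig.nodata_mask], atol=1e-5)
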