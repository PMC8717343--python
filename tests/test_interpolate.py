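"""IDW, RBF and kriging predictors, LOOCV and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from bathysdm import interpolate as I
from bathysdm.soundings import SoundingSet
from bathysdm.variogram import VariogramModel

from conftest import scatter_soundings


def _grid_over(s, cell=10.0):
    xy = s.xy
    return I.make_grid((xy[:, 0].min(), xy[:, 1].min(),
                        xy[:, 0].max(), xy[:, 1].max()), cell)


@pytest.fixture
def plane_soundings():
    return scatter_soundings(40, seed=3, values=lambda p: 2 * p[:, 0] + 3)


class TestIDW:
    def test_hand_computed_two_point_predictions(self):
        s = SoundingSet(pd.DataFrame({"x": [0.0, 0.0], "y": [1.0, 2.0],
                                      "t": [0.0, 1.0], "depth": [0.0, 3.0]}))
        pts, z, tree = I._prep(s)
        q = np.array([[0.0, 0.0]])
        # d=1 (z=0) and d=2 (z=3): p=1 -> 1.0, p=2 -> 0.6
        assert I._idw_values(pts, z, tree, q, 1.0, 2)[0] == pytest.approx(1.0)
        assert I._idw_values(pts, z, tree, q, 2.0, 2)[0] == pytest.approx(0.6)

    def test_single_datum_predicts_constant_surface(self):
        s = SoundingSet(pd.DataFrame({"x": [5.0], "y": [5.0], "t": [0.0],
                                      "depth": [5.0]}))
        grid = I.make_grid((0, 0, 10, 10), 2.0)
        out = I.idw_predict(s, grid, power=2.0, n_neighbors=5)
        np.testing.assert_allclose(out.values, 5.0)

    def test_exact_hit_returns_datum(self, smooth_soundings):
        s = smooth_soundings
        pts, z, tree = I._prep(s)
        pred = I._idw_values(pts, z, tree, pts[:10], 2.0, 10)
        np.testing.assert_allclose(pred, z[:10], atol=1e-9)

    def test_predictions_bounded_by_neighborhood_extremes(self, smooth_soundings):
        s = smooth_soundings
        pts, z, tree = I._prep(s)
        rng = np.random.default_rng(0)
        q = rng.uniform(0, 100, (50, 2))
        k = 8
        pred = I._idw_values(pts, z, tree, q, 3.0, k)
        _, idx = tree.query(q, k=k)
        assert (pred >= z[idx].min(axis=1) - 1e-12).all()
        assert (pred <= z[idx].max(axis=1) + 1e-12).all()

    def test_large_power_approaches_nearest_neighbor(self, smooth_soundings):
        s = smooth_soundings
        pts, z, tree = I._prep(s)
        rng = np.random.default_rng(1)
        q = rng.uniform(0, 100, (30, 2))
        pred = I._idw_values(pts, z, tree, q, 50.0, 10)
        d, nn = tree.query(q, k=2)
        # generic queries only: near-ties between the two closest data points
        # legitimately split the weight at any finite power
        generic = d[:, 1] / d[:, 0] >= 1.2
        assert generic.sum() >= 20
        np.testing.assert_allclose(pred[generic], z[nn[generic, 0]], atol=1e-3)


class TestRBF:
    @pytest.mark.parametrize("basis", ["M", "CRS"])
    def test_plane_reproduced_through_polynomial_part(self, basis, plane_soundings):
        grid = _grid_over(plane_soundings, cell=7.0)
        out = I.rbf_predict(plane_soundings, grid, basis=basis, delta=1.0,
                            robustness=0.0, n_neighbors=15)
        gx, _ = out.centre_mesh()
        np.testing.assert_allclose(out.values, 2 * gx + 3, atol=1e-6)

    @pytest.mark.parametrize("basis", ["M", "CRS"])
    def test_exact_at_data_locations_without_smoothing(self, basis, smooth_soundings):
        pts, z, tree = I._prep(smooth_soundings)
        pred = I._rbf_values(pts, z, tree, pts[:10], basis, 1.0, 0.0, 15)
        np.testing.assert_allclose(pred, z[:10], atol=1e-6)

    def test_local_solution_matches_global_system(self, smooth_soundings):
        # with the neighborhood covering all 50 points, the local solve must
        # agree with a dense global solve
        pts, z, tree = I._prep(smooth_soundings)
        rng = np.random.default_rng(2)
        q = rng.uniform(10, 90, (25, 2))
        local = I._rbf_values(pts, z, tree, q, "M", 1.0, 0.0, 50)
        r = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        phi = I._rbf_kernel(r, "M", 1.0)
        P = np.column_stack([np.ones(len(pts)), pts])
        A = np.block([[phi, P], [P.T, np.zeros((3, 3))]])
        sol = np.linalg.solve(A, np.concatenate([z, np.zeros(3)]))
        rq = np.sqrt(((q[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        globl = I._rbf_kernel(rq, "M", 1.0) @ sol[:len(pts)] + \
            np.column_stack([np.ones(len(q)), q]) @ sol[len(pts):]
        assert np.max(np.abs(local - globl)) < 0.05

    def test_crs_kernel_is_zero_at_origin(self):
        assert I._rbf_kernel(np.array([0.0]), "CRS", 2.0)[0] == 0.0


class TestOptimizeRBF:
    def test_single_candidate_grids_return_that_candidate(self, smooth_soundings):
        cfg = I.optimize_rbf(smooth_soundings, "M", 15, [2.0], [0.5])
        assert cfg.delta == 2.0 and cfg.robustness == 0.5

    def test_noiseless_plane_prefers_no_smoothing(self, plane_soundings):
        # a plane is reproduced exactly at every ridge value, so the
        # smallest-robustness tie-break must win
        cfg = I.optimize_rbf(plane_soundings, "M", 15, [1.0],
                             [0.0, 0.1, 1.0])
        assert cfg.robustness == 0.0

    def test_noisy_data_selects_positive_smoothing_in_most_seeds(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = scatter_soundings(
                120, seed=seed,
                values=lambda p: 50 + p[:, 0] / 10 + rng.normal(0, 0.5, len(p)))
            cfg = I.optimize_rbf(s, "M", 20, [1.0], [0.0, 0.5, 2.0], seed=seed)
            wins += cfg.robustness > 0
        assert wins >= 8


class TestKriging:
    def test_ordinary_weights_reproduce_constant_field(self, smooth_soundings):
        # sum(lambda) = 1 <=> a constant field is predicted exactly
        pts, _, tree = I._prep(smooth_soundings)
        zc = np.full(len(pts), 7.0)
        vm = VariogramModel(0.0, 4.0, 50.0)
        rng = np.random.default_rng(3)
        q = rng.uniform(0, 100, (40, 2))
        pred, _ = I._krige_values(pts, zc, tree, q, vm, 0, 12)
        np.testing.assert_allclose(pred, 7.0, atol=1e-8)

    def test_pure_nugget_model_predicts_neighborhood_mean(self, smooth_soundings):
        pts, z, tree = I._prep(smooth_soundings)
        vm = VariogramModel(1.0, 0.0, 100.0)
        rng = np.random.default_rng(4)
        q = rng.uniform(10, 90, (20, 2))
        k = 10
        pred, _ = I._krige_values(pts, z, tree, q, vm, 0, k)
        _, idx = tree.query(q, k=k)
        np.testing.assert_allclose(pred, z[idx].mean(axis=1), atol=1e-8)

    def test_zero_nugget_kriging_is_exact_with_zero_error(self, smooth_soundings):
        pts, z, tree = I._prep(smooth_soundings)
        vm = VariogramModel(0.0, 4.0, 50.0)
        pred, se = I._krige_values(pts, z, tree, pts[:10], vm, 0, 15)
        np.testing.assert_allclose(pred, z[:10], atol=1e-6)
        np.testing.assert_allclose(se, 0.0, atol=1e-6)

    def test_translation_equivariance(self, smooth_soundings):
        pts, z, tree = I._prep(smooth_soundings)
        vm = VariogramModel(0.0, 4.0, 50.0)
        rng = np.random.default_rng(5)
        q = rng.uniform(10, 90, (20, 2))
        base, _ = I._krige_values(pts, z, tree, q, vm, 1, 15)
        shift = np.array([123456.0, -98765.0])
        tree2 = cKDTree(pts + shift)
        moved, _ = I._krige_values(pts + shift, z, tree2, q + shift, vm, 1, 15)
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_anisotropic_model_weights_continuity_axis(self):
        # two equidistant data points; the one along the major axis must get
        # more weight, i.e. pull the prediction toward its value
        s = SoundingSet(pd.DataFrame(
            {"x": [100.0, 0.0, 900.0], "y": [0.0, 100.0, 900.0],
             "t": [0.0, 1.0, 2.0], "depth": [0.0, 10.0, 5.0]}))
        pts, z, tree = I._prep(s)
        vm = VariogramModel(0.0, 4.0, 300.0, anisotropy_angle=90.0,
                            anisotropy_ratio=0.3)
        pred, _ = I._krige_values(pts, z, tree, np.array([[0.0, 0.0]]), vm, 0, 3)
        assert pred[0] < 5.0  # closer (in effective distance) to depth 0


class TestLOOCVAndSelection:
    def test_idw_loocv_matches_naive_reimplementation(self):
        s = scatter_soundings(30, seed=11)
        cfg = I.InterpConfig("IDW", power=3.0, n_neighbors=8)
        report = I.loocv(s, cfg)
        pts, z, _ = I._prep(s)
        naive = np.empty(30)
        for i in range(30):
            keep = np.arange(30) != i
            sub_pts, sub_z = pts[keep], z[keep]
            d = np.sqrt(((sub_pts - pts[i]) ** 2).sum(1))
            nn = np.argsort(d)[:8]
            w = d[nn] ** -3.0
            naive[i] = (w * sub_z[nn]).sum() / w.sum()
        np.testing.assert_allclose(report.residuals, naive - z, atol=1e-10)

    def test_exact_interpolator_has_near_zero_rmse_on_smooth_data(self, smooth_soundings):
        vm = VariogramModel(0.0, 25.0, 80.0)
        cfg = I.InterpConfig("OK", n_neighbors=20, variogram=vm)
        report = I.loocv(smooth_soundings, cfg)
        assert report.rmse < 0.2  # smooth field, dense support
        assert report.ase is not None
        assert report.selection_score == pytest.approx(abs(report.ase - report.rmse))

    def test_selection_ranks_by_rmse_within_idw_family(self):
        def rep(rmse, method="IDW", ase=None):
            cfg = I.InterpConfig(method, n_neighbors=10,
                                 variogram=VariogramModel(0.0, 1.0, 100.0)
                                 if method in ("OK", "UK1", "UK2") else None)
            score = abs(ase - rmse) if ase is not None else rmse
            return I.CVReport(cfg, np.zeros(5), rmse, ase, score)

        ranked = I.select_best([rep(0.40), rep(0.33)])
        assert ranked[0].rmse == 0.33

    def test_kriging_family_ranked_by_calibration_gap_not_rmse(self):
        vm = VariogramModel(0.0, 1.0, 100.0)
        a = I.CVReport(I.InterpConfig("OK", n_neighbors=10, variogram=vm),
                       np.zeros(5), 0.30, 0.40, 0.10)
        b = I.CVReport(I.InterpConfig("UK1", n_neighbors=10, variogram=vm),
                       np.zeros(5), 0.35, 0.38, 0.03)
        ranked = I.select_best([a, b])
        assert ranked[0].config.method == "UK1"

    def test_single_report_ranks_first_and_empty_raises(self):
        r = I.CVReport(I.InterpConfig("IDW"), np.zeros(3), 0.5, None, 0.5)
        assert I.select_best([r])[0] is r
        with pytest.raises(ValueError):
            I.select_best([])


class TestConfigValidation:
    def test_kriging_requires_variogram_and_enough_neighbors(self):
        with pytest.raises(ValueError, match="variogram"):
            I.InterpConfig("UK1")
        with pytest.raises(ValueError, match="neighbors"):
            I.InterpConfig("UK2", n_neighbors=5,
                           variogram=VariogramModel(0.0, 1.0, 100.0))

    def test_idw_power_must_be_positive(self):
        with pytest.raises(ValueError):
            I.InterpConfig("IDW", power=0.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            I.InterpConfig("SPLINE")
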