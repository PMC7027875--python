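"""PLSR fitting, cross-validation schemes, skill metrics and trait mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitscape as ts
from traitscape.cube import SpectraCube
from traitscape.grids import Grid, Raster
from traitscape.plsr import (
    TraitRaster,
    cross_validate,
    fit_plsr,
    mosaic,
    pct_rmse,
    predict_map,
    r2,
    rmse,
    select_components,
)
from traitscape.preprocess import CalibrationTable

from conftest import clustered_noise_table


def simple_table(X, y, tree_ids=None):
    n = X.shape[0]
    ids = [f"T{i:03d}" for i in range(n)] if tree_ids is None else tree_ids
    meta = pd.DataFrame({"tree_id": ids, "flight_id": "F1", "x": 0.0, "y": 0.0})
    return CalibrationTable(
        np.asarray(X, float), np.arange(X.shape[1], dtype=float) + 500.0,
        meta, pd.DataFrame({"N_pct": y}), {"counts": {}, "pipeline": []},
    )


class TestFitPLSR:
    def test_single_band_linear_response_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 30)
        y = 2.0 + 3.0 * x
        model = fit_plsr(simple_table(x[:, None], y), "N_pct", 1)
        assert np.allclose(model.predict(x[:, None]), y, atol=1e-10)

    def test_zero_components_predicts_mean(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (20, 5))
        y = rng.uniform(1, 3, 20)
        model = fit_plsr(simple_table(X, y), "N_pct", 0)
        assert np.allclose(model.predict(X), y.mean())

    def test_full_rank_equals_ols_oracle(self):
        # 5 orthogonal informative bands; at 5 components PLSR spans the
        # same space as OLS.  Oracle: statsmodels OLS.
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        beta = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        y = Q @ beta + 0.01 * rng.normal(size=40)
        model = fit_plsr(simple_table(Q, y), "N_pct", 5)
        ols = sm.OLS(y, sm.add_constant(Q)).fit()
        yhat_ols = ols.predict(sm.add_constant(Q))
        assert np.allclose(model.predict(Q), yhat_ols, atol=1e-8)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(3).uniform(0, 1, (10, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(simple_table(X, np.full(10, 2.0)), "N_pct", 1)

    def test_log_transform_round_trip(self):
        # noiseless exponential trait-spectrum link: y = exp(a + b x)
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 25)
        y = np.exp(0.5 + 2.0 * x)
        model = fit_plsr(simple_table(x[:, None], y), "N_pct", 1, transform="log")
        assert np.allclose(model.predict(x[:, None]), y, rtol=1e-10)

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(5).uniform(0, 1, (6, 3))
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="n_components"):
            fit_plsr(simple_table(X, y), "N_pct", 6)


class TestMetrics:
    def test_rmse_perfect_and_unit(self):
        assert rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert rmse(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == 1.0

    def test_rmse_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        acc = 0.0
        for a, b in zip(y, yhat):
            acc += (a - b) ** 2
        assert rmse(y, yhat) == pytest.approx(np.sqrt(acc / 50), abs=1e-12)

    def test_pct_rmse_relative_to_mean(self):
        y = np.array([2.0, 2.0, 2.0])
        yhat = np.array([1.0, 2.0, 3.0])
        assert pct_rmse(y, yhat) == pytest.approx(100 * np.sqrt(2 / 3) / 2)

    def test_r2_boundaries(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, y) == 100.0
        assert r2(y, np.full(3, y.mean())) == 0.0

    def test_r2_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
        sst = sum((a - y.mean()) ** 2 for a in y)
        assert r2(y, yhat) == pytest.approx((1 - sse / sst) * 100, abs=1e-10)

    def test_r2_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r2(np.full(5, 1.0), np.arange(5.0))


class TestSelectComponents:
    def test_strictly_decreasing_tiny_se_takes_argmin(self):
        curve = np.array([10.0, 8.0, 6.0, 4.0])
        assert select_components(curve, 1e-9) == 3

    def test_flat_curve_takes_fewest(self):
        assert select_components(np.array([5.0, 5.0, 5.0]), 0.0, np.arange(1, 4)) == 1

    def test_hand_evaluated_one_se_rule(self):
        # best 4.79 at k=4, SE 0.5 -> threshold 5.29 -> smallest k with
        # error <= 5.29 is k=2 (error 5.0)
        curve = np.array([10.0, 5.0, 4.8, 4.79])
        assert select_components(curve, 0.5, np.arange(1, 5)) == 2

    def test_never_exceeds_argmin(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            curve = rng.uniform(1, 10, 8)
            k = select_components(curve, rng.uniform(0, 2))
            assert k <= int(np.argmin(curve))


class TestCrossValidate:
    def test_schemes_coincide_with_one_pixel_per_tree(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (3, 4))
        y = np.array([1.0, 2.0, 3.0])
        t = simple_table(X, y)
        lopo = cross_validate(t, "N_pct", "LOPO", max_components=1, transform="identity")
        loto = cross_validate(t, "N_pct", "LOTO", max_components=1, transform="identity")
        assert np.allclose(lopo.cv_curve, loto.cv_curve)
        assert np.allclose(lopo.yhat, loto.yhat)

    def test_loto_with_single_tree_rejected(self):
        X = np.random.default_rng(10).uniform(0, 1, (5, 3))
        t = simple_table(X, np.arange(5.0), tree_ids=["T0"] * 5)
        with pytest.raises(ValueError, match="one tree"):
            cross_validate(t, "N_pct", "LOTO")

    def test_folds_partition_rows(self, calib_table):
        cv = cross_validate(calib_table, "N_pct", "LOTO", max_components=4)
        assert cv.groups.size == cv.y.size
        assert cv.n_folds == calib_table.n_trees

    def test_lopo_beats_loto_under_shared_crown_noise(self):
        """Within-crown shared spectral noise inflates LOPO skill: the
        one-sided sign test over 20 seeds must reject equality."""
        wins = 0
        for seed in range(20):
            t = clustered_noise_table(seed)
            lopo = cross_validate(t, "N_pct", "LOPO", max_components=6, transform="identity")
            loto = cross_validate(t, "N_pct", "LOTO", max_components=6, transform="identity")
            wins += (lopo.r2 or -np.inf) > (loto.r2 or -np.inf)
        p = stats.binomtest(wins, 20, 0.5, alternative="greater").pvalue
        assert p < 0.05

    def test_noiseless_invertible_link_gives_high_loto_r2(self, landscape):
        cfg = ts.SyntheticSpectraConfig(
            features={"N_pct": (1510.0, 40.0, 0.04)},
            brightness_sd=0.0, pixel_noise_sd=0.0, crown_effect_sd=0.0,
        )
        surf = Raster(landscape.grid, np.full(landscape.grid.shape, 2.0), "N_pct")
        crowns = ts.generate_crown_set(
            landscape, 25, {"N_pct": surf}, seed=17,
            config=ts.CrownConfig(deviation_sd={"N_pct": 0.4}),
        )
        cube = ts.simulate_spectra(
            crowns, cfg, seed=1, pixel_size=4.0, only_crown_neighborhoods=True,
        )
        table = ts.build_calibration_table(cube, landscape.tch, crowns)
        cv = cross_validate(table, "N_pct", "LOTO", max_components=4)
        assert cv.r2 is not None and cv.r2 > 95.0


def constant_cube(wavelengths, spectrum, grid, pixel_size=10.0):
    xs = np.arange(pixel_size / 2, grid.ncols * grid.cell_size, pixel_size)
    ys = np.arange(pixel_size / 2, grid.nrows * grid.cell_size, pixel_size)
    XX, YY = np.meshgrid(xs, ys)
    xy = np.column_stack([XX.ravel(), YY.ravel()])
    refl = np.tile(spectrum, (xy.shape[0], 1))
    return SpectraCube(wavelengths, refl, xy, pixel_size=pixel_size, solar_zenith=30.0)


class TestPredictMap:
    def make_model(self, k=1):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.55, 0.9, 30)  # NIR high enough that NDVI >= 0.75
        # two bands so NDVI can pass: band 0 = red-like, band 1 = nir-like
        X = np.column_stack([0.05 * np.ones(30), x])
        y = 1.0 + 2.0 * x
        t = simple_table(X, y)
        t.wavelengths = np.array([650.0, 860.0])
        return fit_plsr(t, "N_pct", k), t

    def test_constant_cube_gives_constant_raster_at_fitted_value(self):
        model, t = self.make_model()
        grid = Grid((3, 3), 100.0)
        spectrum = t.spectra[4]
        cube = constant_cube(model.wavelengths, spectrum, grid)
        chm = Raster(grid, np.full(grid.shape, 30.0))
        out = predict_map(model, cube, chm, grid=grid)
        expected = model.predict(spectrum[None, :])[0]
        assert np.allclose(out.raster.values, expected)

    def test_zero_component_model_maps_training_mean(self):
        model, t = self.make_model(k=0)
        grid = Grid((3, 3), 100.0)
        cube = constant_cube(model.wavelengths, t.spectra[0], grid)
        chm = Raster(grid, np.full(grid.shape, 30.0))
        out = predict_map(model, cube, chm, grid=grid)
        assert np.allclose(out.raster.values, t.traits["N_pct"].mean())

    def test_low_vegetation_cells_missing_not_zero(self):
        model, t = self.make_model()
        grid = Grid((3, 3), 100.0)
        cube = constant_cube(model.wavelengths, t.spectra[4], grid)
        chm_vals = np.full(grid.shape, 30.0)
        chm_vals[0, 0] = 2.0  # below the 4 m rule
        out = predict_map(model, cube, Raster(grid, chm_vals), grid=grid)
        assert np.isnan(out.raster.values[0, 0])
        assert np.isfinite(out.raster.values[1:, :]).all()

    def test_wavelength_mismatch_rejected(self):
        model, t = self.make_model()
        grid = Grid((3, 3), 100.0)
        cube = constant_cube(np.array([600.0, 900.0]), t.spectra[0], grid)
        chm = Raster(grid, np.full(grid.shape, 30.0))
        with pytest.raises(ValueError, match="wavelength"):
            predict_map(model, cube, chm, grid=grid)

    def test_noiseless_landscape_round_trip(self, flat_landscape):
        """Cell means of the mapped trait match the generative surface."""
        grid = flat_landscape.grid
        vals = 2.0 + 0.3 * np.linspace(0, 1, grid.nrows)[:, None] * np.ones(grid.shape)
        surf = Raster(grid, vals, "N_pct")
        cfg = ts.SyntheticSpectraConfig(
            features={"N_pct": (1510.0, 40.0, 0.04)},
            brightness_sd=0.0, pixel_noise_sd=0.0, crown_effect_sd=0.0,
        )
        crowns = ts.generate_crown_set(
            flat_landscape, 20, {"N_pct": surf}, seed=23,
            config=ts.CrownConfig(deviation_sd={"N_pct": 0.3}),
        )
        calib = ts.simulate_spectra(
            crowns, cfg, seed=2, pixel_size=4.0, only_crown_neighborhoods=True,
        )
        table = ts.build_calibration_table(calib, flat_landscape.tch, crowns)
        model = fit_plsr(table, "N_pct", 1, transform="identity")
        full = ts.simulate_spectra(
            crowns, cfg, seed=3, landscape=flat_landscape, trait_surfaces={"N_pct": surf},
            pixel_size=10.0,
        )
        out = predict_map(model, full, flat_landscape.tch, grid=grid)
        ok = np.isfinite(out.raster.values)
        assert ok.all()
        rel = np.abs(out.raster.values - surf.values) / surf.values
        # crown cells mix tree deviations into the cell mean; compare off-crown cells
        assert np.median(rel) < 0.02


class TestMosaic:
    def grid_raster(self, values, trait="N_pct"):
        g = Grid((2, 2), 100.0)
        vals = np.asarray(values, float)
        return TraitRaster(Raster(g, vals, trait), trait, np.isfinite(vals).astype(int))

    def test_single_raster_identity(self):
        tr = self.grid_raster([[1.0, 2.0], [3.0, np.nan]])
        out = mosaic([tr])
        assert np.allclose(out.raster.values, tr.raster.values, equal_nan=True)

    def test_two_constant_rasters_average(self):
        out = mosaic([self.grid_raster(np.ones((2, 2))), self.grid_raster(3 * np.ones((2, 2)))])
        assert np.allclose(out.raster.values, 2.0)

    def test_partial_overlap_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        rasters = []
        vals = []
        for _ in range(3):
            v = rng.uniform(0, 1, (2, 2))
            v[rng.integers(2), rng.integers(2)] = np.nan
            vals.append(v)
            rasters.append(self.grid_raster(v))
        out = mosaic(rasters)
        for i in range(2):
            for j in range(2):
                cell = [v[i, j] for v in vals if np.isfinite(v[i, j])]
                if cell:
                    assert out.raster.values[i, j] == pytest.approx(np.mean(cell))
                    assert out.n_contributions[i, j] == len(cell)
                else:
                    assert np.isnan(out.raster.values[i, j])

    def test_order_invariant(self):
        rng = np.random.default_rng(13)
        rs = [self.grid_raster(rng.uniform(0, 1, (2, 2))) for _ in range(3)]
        a = mosaic(rs).raster.values
        b = mosaic(rs[::-1]).raster.values
        assert np.allclose(a, b)

    def test_disjoint_grids_rejected(self):
        g2 = Grid((3, 3), 100.0)
        other = TraitRaster(Raster(g2, np.ones((3, 3)), "N_pct"), "N_pct", np.ones((3, 3), int))
        with pytest.raises(ValueError, match="grid"):
            mosaic([self.grid_raster(np.ones((2, 2))), other])
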