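"""DI, AOA threshold/mask and the monotone expected-error calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from marshstock import (
    aoa_mask,
    aoa_threshold,
    build_space,
    calibrate_error,
    di,
    expected_error_surface,
    pixel_di,
    random_folds,
    training_di,
)
from marshstock.spatial_cv import CVResult
from marshstock.uncertainty import ErrorModel, PredictorSpace
from sklearn.isotonic import IsotonicRegression

from conftest import make_training_frame


class _StubModel:
    """Identity design matrix over chosen columns (for hand-computable DI)."""

    def __init__(self, columns):
        self.columns = list(columns)

    def design_matrix(self, frame):
        return frame[self.columns].to_numpy(dtype=float)


def unit_space(columns, dim=None):
    dim = dim or len(columns)
    return PredictorSpace(
        names=list(columns),
        mean=np.zeros(dim),
        sd=np.ones(dim),
        weight=np.full(dim, 1.0 / dim),
        model=_StubModel(columns),
    )


class TestDI:
    def test_hand_computed_collinear_example(self):
        """Training {0,1,2} in 1-D, query at 4: DI = 2 / (4/3) = 1.5."""
        space = unit_space(["x"])
        ref = make_training_frame([0.0, 1.0, 2.0])
        query = pd.DataFrame({"x": [4.0]})
        assert di(query, space, ref)[0] == pytest.approx(1.5)

    def test_zero_iff_identical_reference_point(self):
        space = unit_space(["x"])
        ref = make_training_frame([0.0, 1.0, 2.0])
        assert di(pd.DataFrame({"x": [1.0]}), space, ref)[0] == 0.0
        assert di(pd.DataFrame({"x": [1.001]}), space, ref)[0] > 0.0

    def test_brute_force_oracle_200x200(self):
        rng = np.random.default_rng(42)
        p = 5
        ref_X = rng.normal(size=(200, p))
        query_X = rng.normal(size=(200, p))
        weights = rng.uniform(0.1, 1.0, p)
        weights /= weights.sum()
        cols = [f"x{i}" for i in range(p)]
        space = PredictorSpace(
            names=cols, mean=np.zeros(p), sd=np.ones(p), weight=weights,
            model=_StubModel(cols),
        )
        ref = pd.DataFrame(ref_X, columns=cols)
        query = pd.DataFrame(query_X, columns=cols)
        got = di(query, space, ref)

        # O(n*m) loop oracle in the weighted space
        Tw = ref_X * weights
        Qw = query_X * weights
        denom = np.mean([
            np.linalg.norm(Tw[i] - Tw[j])
            for i in range(len(Tw)) for j in range(i + 1, len(Tw))
        ])
        expected = np.array([
            min(np.linalg.norm(Qw[i] - Tw[j]) for j in range(len(Tw))) / denom
            for i in range(len(Qw))
        ])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_same_fold_exclusion(self):
        space = unit_space(["x"])
        ref = make_training_frame([0.0, 0.1, 5.0])
        q = ref[["x"]]
        # without exclusion every training point matches itself: DI = 0
        np.testing.assert_array_equal(di(q, space, ref), np.zeros(3))
        folds = np.array([1, 1, 2])
        excl = di(q, space, ref, query_folds=folds, reference_folds=folds)
        assert (excl > 0).all()
        with pytest.raises(ValueError):
            di(q, space, ref, query_folds=np.array([3, 3, 3]), reference_folds=np.array([3, 3, 3]))


class TestBuildSpace:
    def test_training_standardized_and_weights_sum_to_one(self, fitted, matrix):
        space = build_space(fitted, matrix)
        T = space.transform(matrix.data)
        sd = np.where(space.sd > 0, space.sd, 1.0)
        recentred = T / space.weight.clip(min=1e-300)  # undo weighting where w>0
        keep = space.weight > 0
        assert np.allclose(recentred[:, keep].mean(axis=0), 0, atol=1e-9)
        assert np.allclose(recentred[:, keep].std(axis=0), 1, atol=1e-9)
        assert space.weight.sum() == pytest.approx(1.0)
        assert sd.shape == space.mean.shape

    def test_rescaling_a_predictor_leaves_space_unchanged(self, matrix, fitted):
        space = build_space(fitted, matrix)
        scaled = matrix.data.copy()
        scaled["elevation"] *= 2.0  # pretend the raw units doubled
        # transform uses training stats; rebuilding from doubled data gives
        # the same standardized coordinates
        space2 = PredictorSpace(
            names=space.names,
            mean=np.where(np.array(space.names) == "elevation", space.mean * 2, space.mean),
            sd=np.where(np.array(space.names) == "elevation", space.sd * 2, space.sd),
            weight=space.weight,
            model=fitted,
        )
        np.testing.assert_allclose(
            space.transform(matrix.data), space2.transform(scaled), atol=1e-12
        )

    def test_zero_variance_dimension_flagged_with_zero_weight(self, matrix):
        from marshstock import ModelSpec, TrainingMatrix, fit

        data = matrix.data.copy()
        data["flat"] = 7.0
        m = TrainingMatrix(data, matrix.covariate_names + ["flat"], matrix.categorical)
        fitted = fit(m, ModelSpec(n_trees=10, seed=0))
        space = build_space(fitted, m)
        i = space.names.index("flat")
        assert space.weight[i] == 0.0
        assert "flat" in space.zero_sd_dims


class TestAOAThreshold:
    def test_quantile_oracle_1234(self):
        assert aoa_threshold(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(5.5)

    def test_constant_values(self):
        assert aoa_threshold(np.full(10, 3.3)) == pytest.approx(3.3)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_matches_direct_quantile_oracle(self, values):
        v = np.array(values)
        q25, q75 = np.quantile(v, [0.25, 0.75])
        assert aoa_threshold(v) == pytest.approx(q75 + 1.5 * (q75 - q25))

    def test_threshold_at_or_above_max_keeps_all_training_inside(self, matrix, fitted):
        folds = random_folds(matrix.locations(), k=5, seed=0)
        space = build_space(fitted, matrix)
        tdi = training_di(matrix, space, folds)
        thr = aoa_threshold(tdi)
        if thr >= tdi.max():
            assert (tdi <= thr).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            aoa_threshold(np.array([1.0, 2.0]))


class TestAOAMask:
    def test_outside_at_one_depth_means_outside_layer(self):
        di_maps = {0.0: np.array([[0.5]]), 30.0: np.array([[2.0]])}
        out = aoa_mask(di_maps, threshold=1.0, layer=(0.0, 30.0))
        assert out["average"][0, 0] == 0.5
        assert not out["inside"][0, 0]

    def test_inside_at_both_depths(self):
        di_maps = {0.0: np.array([[0.5]]), 30.0: np.array([[0.9]])}
        out = aoa_mask(di_maps, threshold=1.0, layer=(0.0, 30.0))
        assert out["inside"][0, 0]

    def test_boundary_di_counts_as_inside(self):
        di_maps = {0.0: np.array([[1.0]]), 30.0: np.array([[1.0]])}
        out = aoa_mask(di_maps, threshold=1.0, layer=(0.0, 30.0))
        assert out["inside"][0, 0]

    def test_missing_depth_rejected(self):
        with pytest.raises(ValueError, match="30"):
            aoa_mask({0.0: np.zeros((1, 1))}, 1.0, (0.0, 30.0))


def synthetic_cv(residuals):
    res = np.asarray(residuals, dtype=float)
    return CVResult(
        samples=pd.DataFrame({"residual": res}),
        r2=0.5, rmse=float(np.sqrt((res**2).mean())), k=5,
    )


class TestCalibrateError:
    def test_homoscedastic_residuals_give_flat_map(self):
        rng = np.random.default_rng(0)
        n = 1000
        di_v = np.sort(rng.uniform(0, 2, n))
        cv = synthetic_cv(rng.normal(0, 0.01, n))
        em = calibrate_error(cv, di_v)
        pred = em.predict(np.linspace(0, 2, 50))
        assert np.abs(pred / cv.rmse - 1).max() < 0.15

    def test_di_proportional_noise_recovered(self):
        rng = np.random.default_rng(1)
        n = 1500
        di_v = np.sort(rng.uniform(0, 2, n))
        sd_true = 0.002 + 0.01 * di_v
        em = calibrate_error(synthetic_cv(rng.normal(0, sd_true)), di_v)
        pred = em.predict(di_v)
        assert spearmanr(pred, sd_true).statistic > 0.9
        fine = em.predict(np.linspace(0, 3, 500))
        assert np.all(np.diff(fine) >= -1e-12)  # monotone non-decreasing

    def test_flat_extrapolation_beyond_fitted_range(self):
        rng = np.random.default_rng(2)
        di_v = np.sort(rng.uniform(0, 1, 300))
        em = calibrate_error(synthetic_cv(rng.normal(0, 0.01, 300)), di_v)
        assert em.predict(np.array([50.0]))[0] == em.predict(np.array([em.di_range[1]]))[0]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            calibrate_error(synthetic_cv(np.ones(5)), np.arange(5), min_window=20)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="align"):
            calibrate_error(synthetic_cv(np.ones(30)), np.arange(29))


def constant_error_model(c: float) -> ErrorModel:
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit([0.0, 1.0], [c, c])
    return ErrorModel(iso=iso, di_range=(0.0, 1.0), window=2, n_samples=2)


class TestExpectedErrorSurface:
    def test_constant_error_closed_form(self, grid, matrix, fitted):
        space = build_space(fitted, matrix)
        c = 0.01
        out = expected_error_surface(grid, space, matrix, constant_error_model(c), (0.0, 30.0))
        np.testing.assert_allclose(out["error"][grid.mask], 30 * 100 * c)

    def test_thickness_scales_error(self, grid, matrix, fitted):
        space = build_space(fitted, matrix)
        em = constant_error_model(0.01)
        shallow = expected_error_surface(grid, space, matrix, em, (0.0, 30.0))
        deep = expected_error_surface(grid, space, matrix, em, (30.0, 100.0))
        ratio = deep["error"][grid.mask] / shallow["error"][grid.mask]
        np.testing.assert_allclose(ratio, 70.0 / 30.0)

    def test_error_monotone_in_pixel_di(self, grid, matrix, fitted):
        rng = np.random.default_rng(3)
        folds = random_folds(matrix.locations(), k=5, seed=3)
        space = build_space(fitted, matrix)
        tdi = training_di(matrix, space, folds)
        cv = synthetic_cv(rng.normal(0, 0.002 + 0.01 * tdi))
        em = calibrate_error(cv, tdi)
        out = expected_error_surface(grid, space, matrix, em, (0.0, 30.0))
        # composition of monotone maps: same-DI ordering carries to errors
        di_mean = (out["di_top"] + out["di_bottom"])[grid.mask] / 2
        err = out["error"][grid.mask]
        order = np.argsort(di_mean)
        e_top_sorted = em.predict(np.sort(out["di_top"][grid.mask]))
        assert np.all(np.diff(e_top_sorted) >= -1e-12)
        # err is a sum of monotone maps of the two depth DIs, which are
        # themselves strongly rank-correlated with their mean
        assert spearmanr(di_mean[order], err[order]).statistic > 0.9


def test_pixel_di_zero_at_training_pixel(grid, matrix, fitted):
    """A pixel whose covariates+depth coincide with a training sample has DI 0."""
    space = build_space(fitted, matrix)
    raster = pixel_di(grid, space, matrix, 15.0)
    row = matrix.data.iloc[0]
    r, c = grid.index_of(row["lon"], row["lat"])
    if row["depth_cm"] == 15.0:
        assert raster[r[0], c[0]] == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(raster[~grid.mask]).all()
    assert (raster[grid.mask] >= 0).all()
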