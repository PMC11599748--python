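"""Spatial CV: distances, distance-matched folds, leakage-free cross-validation."""

import numpy as np
import pandas as pd
import pytest

from marshstock import (
    GenerativeOCDParams,
    ModelSpec,
    SamplingDesign,
    TrainingMatrix,
    cross_validate,
    extract_covariates,
    haversine_km,
    knndm_folds,
    nnd_ecdf,
    random_folds,
    sample_cores,
    sample_prediction_points,
)
from marshstock.spatial_cv import FoldAssignment, fold_quality


def coords(points):
    return pd.DataFrame(points, columns=["lon", "lat"])


class TestHaversine:
    def test_one_degree_on_equator(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.2, abs=0.5)

    def test_symmetry_and_zero(self):
        assert haversine_km(10, 20, 10, 20) == 0.0
        assert haversine_km(0, 0, 5, 5) == pytest.approx(haversine_km(5, 5, 0, 0))


class TestNNDEcdf:
    def test_single_pair_closed_form(self):
        d = nnd_ecdf(coords([(0.0, 0.0)]), coords([(1.0, 0.0)]))
        assert d[0] == pytest.approx(111.2, abs=0.5)

    def test_subset_without_self_exclusion_is_zero(self):
        pts = coords([(0, 0), (1, 1), (2, 2)])
        np.testing.assert_array_equal(nnd_ecdf(pts, pts), np.zeros(3))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        a = coords(np.column_stack([rng.uniform(0, 10, 100), rng.uniform(40, 50, 100)]))
        b = coords(np.column_stack([rng.uniform(0, 10, 100), rng.uniform(40, 50, 100)]))
        got = nnd_ecdf(a, b)
        # O(n^2) loop oracle
        expected = np.sort([
            min(haversine_km(a["lon"][i], a["lat"][i], b["lon"][j], b["lat"][j])
                for j in range(len(b)))
            for i in range(len(a))
        ])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_self_exclusion(self):
        pts = coords([(0, 0), (1, 0)])
        d = nnd_ecdf(pts, pts, exclude_self=True)
        assert (d > 100).all()


class TestSamplePredictionPoints:
    def test_all_points_on_mask_and_deterministic(self, grid):
        p1 = sample_prediction_points(grid, n=200, seed=5)
        p2 = sample_prediction_points(grid, n=200, seed=5)
        pd.testing.assert_frame_equal(p1, p2)
        r, c = grid.index_of(p1["lon"].to_numpy(), p1["lat"].to_numpy())
        assert grid.mask[r, c].all()

    def test_oversized_request_returns_all_with_warning(self, grid):
        n_mask = int(grid.mask.sum())
        with pytest.warns(UserWarning):
            pts = sample_prediction_points(grid, n=n_mask + 1, seed=0)
        assert len(pts) == n_mask


class TestKnndmFolds:
    def test_well_separated_clusters_become_folds(self):
        """Enumeration oracle: with k far-apart clusters and distant prediction
        points, the optimal assignment is exactly the cluster partition."""
        cluster_offsets = [(0.0, 40.0), (5.0, 40.0), (10.0, 40.0)]
        pts, truth = [], []
        for ci, (ox, oy) in enumerate(cluster_offsets):
            for j in range(4):
                pts.append((ox + 0.01 * j, oy + 0.01 * j))
                truth.append(ci)
        train = coords(pts)
        train["location_id"] = [f"p{i}" for i in range(len(train))]
        pred = coords([(20.0 + i, 45.0) for i in range(5)])
        fa = knndm_folds(train[["location_id", "lon", "lat"]], pred, k=3)
        labels = fa.fold_of(train["location_id"])
        # same partition: identical fold <=> identical cluster
        same_fold = labels[:, None] == labels[None, :]
        same_cluster = np.asarray(truth)[:, None] == np.asarray(truth)[None, :]
        np.testing.assert_array_equal(same_fold, same_cluster)

    def test_quality_beats_random_on_clustered_data(self, cores, grid, matrix):
        locs = matrix.locations()
        pred = sample_prediction_points(grid, n=500, seed=0)
        kn = knndm_folds(locs, pred, k=5)
        rn = random_folds(locs, k=5, seed=0)
        assert kn.quality <= fold_quality(rn, locs, pred)
        assert kn.quality == pytest.approx(fold_quality(kn, locs, pred))

    def test_seeded_determinism(self, matrix, grid):
        locs = matrix.locations()
        pred = sample_prediction_points(grid, n=300, seed=1)
        a = knndm_folds(locs, pred, k=5, seed=1)
        b = knndm_folds(locs, pred, k=5, seed=1)
        pd.testing.assert_series_equal(a.folds, b.folds)
        assert a.quality == b.quality

    def test_k_larger_than_locations_rejected(self):
        train = coords([(0, 0), (1, 1)])
        train["location_id"] = ["a", "b"]
        with pytest.raises(ValueError):
            knndm_folds(train, coords([(5, 5)]), k=3)


class TestRandomFolds:
    def test_fold_sizes_differ_by_at_most_one(self, matrix):
        fa = random_folds(matrix.locations(), k=5, seed=2)
        sizes = fa.folds.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert len(sizes) == 5

    def test_seeded_determinism(self, matrix):
        a = random_folds(matrix.locations(), k=4, seed=3)
        b = random_folds(matrix.locations(), k=4, seed=3)
        pd.testing.assert_series_equal(a.folds, b.folds)

    def test_depth_samples_never_split_across_folds(self, matrix):
        fa = random_folds(matrix.locations(), k=5, seed=4)
        sample_folds = fa.fold_of(matrix.location_ids)
        per_loc = pd.DataFrame(
            {"loc": matrix.location_ids, "fold": sample_folds}
        ).groupby("loc")["fold"].nunique()
        assert (per_loc == 1).all()


class TestFoldAssignmentInvariants:
    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            FoldAssignment(folds=pd.Series([1, 1, 1], index=["a", "b", "c"]), k=2)

    def test_duplicate_location_rejected(self):
        with pytest.raises(ValueError, match="exactly once"):
            FoldAssignment(folds=pd.Series([1, 2], index=["a", "a"]), k=2)


class TestCrossValidate:
    def test_noiseless_linear_truth_recovered(self, grid):
        params = GenerativeOCDParams(
            intercept=0.03,
            covariate_effects={"elevation": -0.008, "ndvi": 0.005, "tidal": 0.003},
            depth_effect=-5e-5, noise_sd=0.0,
        )
        design = SamplingDesign(n_locations=400, n_clusters=3, cluster_fraction=0.5,
                                cluster_sd=0.05, deep_retention=1.0, seed=6)
        m = extract_covariates(sample_cores(grid, params, design), grid)
        pred = sample_prediction_points(grid, n=500, seed=6)
        folds = knndm_folds(m.locations(), pred, k=5)
        cv = cross_validate(m, folds, ModelSpec(n_trees=100, seed=6))
        assert cv.r2 > 0.95

    def test_shuffled_response_has_no_skill(self, matrix, grid):
        rng = np.random.default_rng(7)
        data = matrix.data.copy()
        data["ocd_gcm3"] = rng.permutation(data["ocd_gcm3"].to_numpy())
        shuffled = TrainingMatrix(data, matrix.covariate_names, matrix.categorical)
        folds = random_folds(matrix.locations(), k=5, seed=7)
        cv = cross_validate(shuffled, folds, ModelSpec(n_trees=100, seed=7))
        assert cv.r2 <= 0.05

    def test_rmse_matches_definition_and_full_coverage(self, matrix):
        folds = random_folds(matrix.locations(), k=5, seed=8)
        cv = cross_validate(matrix, folds, ModelSpec(n_trees=50, seed=8))
        res = cv.samples["residual"].to_numpy()
        assert cv.rmse == pytest.approx(np.sqrt(np.mean(res**2)))
        assert len(cv.samples) == len(matrix)  # every sample predicted once
        assert cv.r2 <= 1

    def test_no_location_leakage(self, matrix):
        """Each held-out prediction comes from a model that saw no sample of
        that location: all samples of a location share one fold label."""
        folds = random_folds(matrix.locations(), k=5, seed=9)
        cv = cross_validate(matrix, folds, ModelSpec(n_trees=20, seed=9))
        fold_by_loc = cv.samples.groupby("location_id")["fold"].nunique()
        assert (fold_by_loc == 1).all()
        merged = cv.samples.merge(folds.to_frame(), on="location_id")
        assert (merged["fold_x"] == merged["fold_y"]).all()
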