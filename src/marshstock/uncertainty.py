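"""Dissimilarity index, area of applicability and expected-error calibration.

The dissimilarity index (DI) of a prediction point is its minimum distance
to the training data in a predictor space that has been centred/scaled
with training statistics and weighted by normalized variable importance,
divided by the mean pairwise distance among all training points. Training
points themselves get a cross-validation-aware DI: the nearest neighbour
is searched only among points of *other* CV folds, mirroring what the
model could actually learn from during validation.

The AOA threshold is the outlier-removed maximum of the training DIs
(Q75 + 1.5 * IQR, linear-interpolation quantiles); pixels whose DI exceeds
it are outside the area of applicability. Per soil layer the AOA indicator
is evaluated at the layer's top and bottom depths and averaged — only
pixels inside at both depths (average 1) count as inside.

Expected error: cross-validation residuals are ordered by DI, a sliding
window turns them into local RMSE estimates, and an isotonic (monotone
non-decreasing) regression maps DI to expected RMSE, extrapolating flat
beyond the fitted range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.isotonic import IsotonicRegression

from marshstock.grids import CovariateGrid
from marshstock.model import FittedModel
from marshstock.spatial_cv import CVResult, FoldAssignment
from marshstock.training import TrainingMatrix


@dataclass
class PredictorSpace:
    """Scaled, importance-weighted predictor space shared by DI and AOA.

    Centring/scaling constants come from the training data only; weights
    are the model's normalized impurity importances. Zero-variance
    dimensions receive weight 0 and are flagged.
    """

    names: list[str]  # expanded (post one-hot) order
    mean: np.ndarray
    sd: np.ndarray
    weight: np.ndarray
    model: FittedModel = field(repr=False)
    zero_sd_dims: list[str] = field(default_factory=list)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        """Map raw predictor rows into the weighted standardized space."""
        X = self.model.design_matrix(frame)
        sd = np.where(self.sd > 0, self.sd, 1.0)
        return (X - self.mean) / sd * self.weight


def build_space(model: FittedModel, matrix: TrainingMatrix) -> PredictorSpace:
    """Derive the DI predictor space from a fitted model and its training data."""
    X = model.design_matrix(matrix.data)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    weight = model.importance.copy()
    zero = sd == 0
    weight[zero] = 0.0
    total = weight.sum()
    if total > 0:
        weight = weight / total
    return PredictorSpace(
        names=list(model.predictor_names),
        mean=mean,
        sd=sd,
        weight=weight,
        model=model,
        zero_sd_dims=[n for n, z in zip(model.predictor_names, zero) if z],
    )


def _mean_pairwise_distance(T: np.ndarray) -> float:
    if len(T) < 2:
        raise ValueError("need at least two training points for the DI denominator")
    return float(pdist(T).mean())


def di(
    query_rows: pd.DataFrame,
    space: PredictorSpace,
    reference_matrix,
    query_folds: np.ndarray | None = None,
    reference_folds: np.ndarray | None = None,
) -> np.ndarray:
    """Dissimilarity index per query row.

    numerator = distance to the nearest reference point in the weighted
    standardized space (skipping same-fold points when both fold vectors
    are given); denominator = mean pairwise distance among *all* reference
    points, computed once. DI = 0 iff an identical predictor vector exists
    in the (non-excluded) reference set.

    ``reference_matrix`` may be a :class:`TrainingMatrix` or a plain
    DataFrame of predictor rows.
    """
    ref = getattr(reference_matrix, "data", reference_matrix)
    T = space.transform(ref)
    denom = _mean_pairwise_distance(T)
    Q = space.transform(query_rows)
    d = cdist(Q, T)

    if query_folds is not None and reference_folds is not None:
        same = np.asarray(query_folds)[:, None] == np.asarray(reference_folds)[None, :]
        if same.all(axis=1).any():
            raise ValueError("a query row has every reference point excluded (same fold)")
        d[same] = np.inf

    return d.min(axis=1) / denom


def training_di(
    matrix: TrainingMatrix, space: PredictorSpace, folds: FoldAssignment
) -> np.ndarray:
    """Cross-validated DI of every training sample (same-fold neighbours excluded)."""
    labels = folds.fold_of(matrix.location_ids)
    return di(matrix.data, space, matrix, query_folds=labels, reference_folds=labels)


def aoa_threshold(training_di_values: np.ndarray) -> float:
    """AOA threshold = Q75 + 1.5 * IQR of the cross-validated training DIs.

    Quantiles use the linear-interpolation convention (numpy default,
    type-7): the threshold value depends on this and it is pinned here.
    """
    v = np.asarray(training_di_values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 training DI values")
    q25, q75 = np.quantile(v, [0.25, 0.75])
    return float(q75 + 1.5 * (q75 - q25))


def aoa_mask(
    di_at_depths: dict[float, np.ndarray],
    threshold: float,
    layer: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Layer AOA from per-depth DI rasters.

    The inside indicator (DI <= threshold; boundary counts as inside) is
    evaluated at the layer's top and bottom depths and averaged; a pixel is
    inside the layer's AOA only when the average equals 1 (inside at both
    depths) — averages of 0 or 0.5 are outside.

    Returns ``{"average": float raster in {0, .5, 1}, "inside": bool raster}``
    (NaN DI propagates to NaN average / outside).
    """
    top, bottom = layer
    for d in (top, bottom):
        if d not in di_at_depths:
            raise ValueError(f"missing DI raster for depth {d} cm")
    ind = {}
    for d in (top, bottom):
        di_r = np.asarray(di_at_depths[d], dtype=float)
        ind[d] = np.where(np.isnan(di_r), np.nan, (di_r <= threshold).astype(float))
    average = (ind[top] + ind[bottom]) / 2.0
    inside = average == 1.0
    return {"average": average, "inside": inside}


@dataclass
class ErrorModel:
    """Monotone non-decreasing map from DI to expected RMSE (g C cm^-3).

    Fitted by isotonic regression on sliding-window RMSEs of CV residuals
    ordered by DI; beyond the fitted DI range it extrapolates flat.
    """

    iso: IsotonicRegression = field(repr=False)
    di_range: tuple[float, float]
    window: int
    n_samples: int

    def predict(self, di_values: np.ndarray) -> np.ndarray:
        v = np.asarray(di_values, dtype=float)
        out = np.full(v.shape, np.nan)
        ok = np.isfinite(v)
        # out_of_bounds="clip" on the isotonic fit realizes the flat extrapolation
        out[ok] = self.iso.predict(np.clip(v[ok], *self.di_range))
        return out


def calibrate_error(
    cv: CVResult,
    training_di_values: np.ndarray,
    window_fraction: float = 0.1,
    min_window: int = 20,
) -> ErrorModel:
    """Fit the DI -> expected RMSE calibration from CV residuals.

    Samples are sorted by DI; a sliding window of
    ``max(min_window, window_fraction * n)`` samples yields local RMSEs at
    the window-median DI; an isotonic regression (monotone non-decreasing)
    is fitted through those points.
    """
    di_v = np.asarray(training_di_values, dtype=float)
    res = cv.samples["residual"].to_numpy(dtype=float)
    if di_v.shape[0] != res.shape[0]:
        raise ValueError("training DI and CV residuals must align by sample")
    n = len(res)
    window = max(min_window, int(round(window_fraction * n)))
    if n < window:
        raise ValueError(f"need at least one window of {window} samples, got {n}")

    order = np.argsort(di_v, kind="stable")
    di_sorted = di_v[order]
    sq = res[order] ** 2
    # rolling mean of squared residuals over the window, one value per position
    kernel = np.ones(window) / window
    rmse_win = np.sqrt(np.convolve(sq, kernel, mode="valid"))
    centre = np.array(
        [np.median(di_sorted[i : i + window]) for i in range(n - window + 1)]
    )

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(centre, rmse_win)
    return ErrorModel(
        iso=iso,
        di_range=(float(centre.min()), float(centre.max())),
        window=window,
        n_samples=n,
    )


def pixel_di(
    grid: CovariateGrid,
    space: PredictorSpace,
    reference_matrix: TrainingMatrix,
    depth: float,
) -> np.ndarray:
    """DI raster over the marsh mask at one standard depth.

    Depth is part of the predictor space, so the DI of a pixel depends on
    the depth at which the prediction is made. Prediction-time DI uses all
    training points (no fold exclusion).
    """
    rows_idx, cols_idx = grid.masked_indices()
    frame = grid.masked_table()
    frame["depth_cm"] = float(depth)
    values = di(frame, space, reference_matrix)
    raster = grid.new_raster()
    raster[rows_idx, cols_idx] = values
    return raster


def expected_error_surface(
    grid: CovariateGrid,
    space: PredictorSpace,
    reference_matrix: TrainingMatrix,
    error_model: ErrorModel,
    layer: tuple[float, float],
    di_at_depths: dict[float, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Expected layer-stock error raster (Mg C ha^-1).

    The OCD-level expected RMSE at the layer's top and bottom depths is
    combined by the identical trapezoid used for the stocks:
    ((e_top + e_bottom) / 2) * thickness_cm * 100 — so the error map is in
    the same units as the prediction map.

    Returns ``{"error": raster, "di_top": raster, "di_bottom": raster}``;
    pass ``di_at_depths`` to reuse already-computed DI rasters.
    """
    top, bottom = layer
    di_at_depths = di_at_depths or {}
    di_top = di_at_depths.get(top)
    if di_top is None:
        di_top = pixel_di(grid, space, reference_matrix, top)
    di_bottom = di_at_depths.get(bottom)
    if di_bottom is None:
        di_bottom = pixel_di(grid, space, reference_matrix, bottom)

    e_top = error_model.predict(di_top)
    e_bottom = error_model.predict(di_bottom)
    error = (e_top + e_bottom) / 2.0 * (bottom - top) * 100.0
    return {"error": error, "di_top": di_top, "di_bottom": di_bottom}
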