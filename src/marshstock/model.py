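"""Depth-augmented random-forest regression for organic carbon density.

OCD (g C cm^-3) is modelled as a function of sample depth plus the
landscape covariates; depth enters as an ordinary predictor so one fitted
ensemble predicts at any standard depth. Defaults are pinned to the final
production settings (mtry 3, minimum node size 5, 300 trees, impurity
importance). Categorical covariates are one-hot expanded and the expansion
map is stored on the model so the uncertainty module works in the
identical predictor space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from marshstock.training import TrainingMatrix

DEFAULT_TUNING_GRID = {
    "mtry": (1, 2, 3, 4, 5),
    "min_node": (1, 2, 3, 5, 10),
    "n_trees": (100, 200, 300, 400, 500),
}


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest hyperparameters.

    mtry: predictors considered per split; min_node: minimum terminal node
    size; importance_mode is fixed to impurity (variance reduction).
    """

    mtry: int = 3
    min_node: int = 5
    n_trees: int = 300
    importance_mode: str = "impurity"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance_mode != "impurity":
            raise ValueError("only impurity importance is supported")


@dataclass
class FittedModel:
    """A fitted ensemble plus everything needed to reproduce its input space."""

    estimator: RandomForestRegressor = field(repr=False)
    predictor_names: list[str]  # expanded (post one-hot) column order
    raw_predictor_names: list[str]
    onehot_map: dict[str, list[float]]  # categorical name -> class codes
    importance_raw: np.ndarray
    importance: np.ndarray  # normalized to sum 1
    spec: ModelSpec
    n_samples: int

    def design_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Expand a raw-predictor frame into the fitted column order.

        Unseen categorical codes expand to all-zero indicator blocks.
        Missing predictor columns raise, naming the column.
        """
        missing = [c for c in self.raw_predictor_names if c not in frame.columns]
        if missing:
            raise ValueError(f"missing predictor column(s): {missing}")
        cols = {}
        for name in self.raw_predictor_names:
            if name in self.onehot_map:
                codes = frame[name].to_numpy(dtype=float)
                for cls in self.onehot_map[name]:
                    cols[f"{name}={cls:g}"] = (codes == cls).astype(float)
            else:
                cols[name] = frame[name].to_numpy(dtype=float)
        X = np.column_stack([cols[c] for c in self.predictor_names])
        return X

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predict OCD (g C cm^-3) per row; clipped at the physical floor of 0."""
        X = self.design_matrix(frame)
        return np.clip(self.estimator.predict(X), 0.0, None)

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": self.predictor_names,
             "importance_raw": self.importance_raw,
             "importance": self.importance}
        ).sort_values("importance", ascending=False, ignore_index=True)


def _expand(matrix: TrainingMatrix) -> tuple[np.ndarray, list[str], dict[str, list[float]]]:
    onehot_map = {
        name: sorted(matrix.data[name].unique().tolist())
        for name in matrix.predictor_names
        if name in matrix.categorical
    }
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name in matrix.predictor_names:
        if name in onehot_map:
            codes = matrix.data[name].to_numpy(dtype=float)
            for cls in onehot_map[name]:
                names.append(f"{name}={cls:g}")
                cols.append((codes == cls).astype(float))
        else:
            names.append(name)
            cols.append(matrix.data[name].to_numpy(dtype=float))
    return np.column_stack(cols), names, onehot_map


def _raw_impurity_importance(forest: RandomForestRegressor) -> np.ndarray:
    """Mean un-normalized impurity (variance) reduction per expanded predictor."""
    total = np.zeros(forest.n_features_in_)
    for tree in forest.estimators_:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def fit(matrix: TrainingMatrix, spec: ModelSpec) -> FittedModel:
    """Fit the random forest on a training matrix.

    Depth is an ordinary predictor. Impurity importances are stored both
    raw and normalized to sum 1 (the normalized vector is what the
    dissimilarity-index weighting uses downstream).
    """
    y = matrix.response.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    X, names, onehot_map = _expand(matrix)

    forest = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=min(spec.mtry, X.shape[1]),
        min_samples_leaf=spec.min_node,
        bootstrap=spec.bootstrap,
        random_state=int(spec.seed) % (2**31 - 1),
        n_jobs=1,
    )
    forest.fit(X, y)

    raw = _raw_impurity_importance(forest)
    total = raw.sum()
    norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    return FittedModel(
        estimator=forest,
        predictor_names=names,
        raw_predictor_names=matrix.predictor_names,
        onehot_map=onehot_map,
        importance_raw=raw,
        importance=norm,
        spec=spec,
        n_samples=len(matrix),
    )


def predict_ocd(model: FittedModel, covariate_rows: pd.DataFrame, depth: float) -> np.ndarray:
    """Predict OCD (g C cm^-3) for covariate rows at one standard depth.

    ``covariate_rows`` needs every raw covariate column; the depth column
    is supplied here as the scalar standard depth (0, 30 or 100 cm for the
    production layers).
    """
    frame = covariate_rows.copy()
    frame["depth_cm"] = float(depth)
    return model.predict(frame)


def tune(
    matrix: TrainingMatrix,
    folds,
    grid: dict[str, tuple] | None = None,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, ModelSpec]:
    """Grid-search hyperparameters by spatial CV RMSE.

    Default grid: mtry 1..5 x min_node {1,2,3,5,10} x trees
    {100..500} (125 combinations). Returns the full tuning table and the
    selected spec — lowest RMSE, ties broken toward fewer trees then
    larger minimum node size (cheaper, smoother models).
    """
    from marshstock.spatial_cv import cross_validate  # deferred: avoid import cycle

    grid = grid or DEFAULT_TUNING_GRID
    if not all(grid.get(k) for k in ("mtry", "min_node", "n_trees")):
        raise ValueError("tuning grid must be non-empty in mtry, min_node and n_trees")

    rows = []
    for mtry, min_node, n_trees in itertools.product(
        grid["mtry"], grid["min_node"], grid["n_trees"]
    ):
        spec = ModelSpec(mtry=mtry, min_node=min_node, n_trees=n_trees, seed=base_seed)
        cv = cross_validate(matrix, folds, spec)
        rows.append({"mtry": mtry, "min_node": min_node, "n_trees": n_trees,
                     "rmse": cv.rmse, "r2": cv.r2})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["rmse", "n_trees", "min_node"], ascending=[True, True, False], kind="stable"
    ).iloc[0]
    selected = ModelSpec(
        mtry=int(best["mtry"]), min_node=int(best["min_node"]),
        n_trees=int(best["n_trees"]), seed=base_seed,
    )
    return table, selected
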