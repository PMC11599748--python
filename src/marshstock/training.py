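"""Assemble and screen the training matrix from core tables and covariate grids."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from marshstock.grids import CovariateGrid

logger = logging.getLogger(__name__)

CORE_COLUMNS = ["location_id", "lon", "lat", "depth_cm", "ocd_gcm3", "region"]


@dataclass
class TrainingMatrix:
    """Depth samples with covariates: the model's training table.

    ``data`` holds one row per depth sample with columns
    ``location_id, lon, lat, region, depth_cm, <covariates...>, ocd_gcm3``.
    Depth is an ordinary predictor; categorical covariates are carried as
    integer class codes (one-hot expansion happens inside the model and
    uncertainty modules so both use the same expansion).
    """

    data: pd.DataFrame
    covariate_names: list[str]
    categorical: frozenset[str]

    def __post_init__(self) -> None:
        missing = set(self.covariate_names) - set(self.data.columns)
        if missing:
            raise ValueError(f"covariate columns missing from data: {sorted(missing)}")
        if self.data[self.covariate_names + ["depth_cm", "ocd_gcm3"]].isna().any().any():
            raise ValueError("training matrix contains missing values")
        if (self.data["depth_cm"] <= 0).any():
            raise ValueError("depths must be positive (layer-centre depths)")

    @property
    def predictor_names(self) -> list[str]:
        return ["depth_cm"] + self.covariate_names

    @property
    def predictors(self) -> pd.DataFrame:
        return self.data[self.predictor_names]

    @property
    def response(self) -> pd.Series:
        return self.data["ocd_gcm3"]

    @property
    def location_ids(self) -> pd.Series:
        return self.data["location_id"]

    def locations(self) -> pd.DataFrame:
        """One row per unique location: location_id, lon, lat."""
        return (
            self.data.groupby("location_id", sort=True)[["lon", "lat"]]
            .first()
            .reset_index()
        )

    def subset(self, row_mask: np.ndarray) -> "TrainingMatrix":
        return TrainingMatrix(
            data=self.data.loc[row_mask].reset_index(drop=True),
            covariate_names=self.covariate_names,
            categorical=self.categorical,
        )

    def __len__(self) -> int:
        return len(self.data)


def filter_sites(
    cores: pd.DataFrame,
    lat_min: float = -60.0,
    lat_max: float = 60.0,
    mask_grid: CovariateGrid | None = None,
) -> pd.DataFrame:
    """Drop cores outside the latitude band and (optionally) off the marsh mask.

    Mirrors the study-area filter: covariate data only exist between
    60° N and 60° S and inside the coastal marsh extent.
    """
    if cores.empty:
        raise ValueError("core table is empty")
    in_band = (cores["lat"] >= lat_min) & (cores["lat"] <= lat_max)
    n_band = int((~in_band).sum())
    kept = cores.loc[in_band]

    n_mask = 0
    if mask_grid is not None and not kept.empty:
        s = mask_grid.spec
        in_bounds = (
            (kept["lon"] >= s.lon_min)
            & (kept["lon"] <= s.lon_max)
            & (kept["lat"] >= s.lat_min)
            & (kept["lat"] <= s.lat_max)
        ).to_numpy()
        on_mask = in_bounds.copy()
        if in_bounds.any():
            row, col = mask_grid.index_of(
                kept["lon"].to_numpy()[in_bounds], kept["lat"].to_numpy()[in_bounds]
            )
            on_mask[in_bounds] = mask_grid.mask[row, col]
        n_mask = int((~on_mask).sum())
        kept = kept.loc[on_mask]

    logger.info("filter_sites: removed %d outside band, %d off mask", n_band, n_mask)
    if kept.empty:
        raise ValueError("all cores removed by site filter")
    return kept.reset_index(drop=True)


def compute_ocd(bulk_density, oc_fraction):
    """Organic carbon density (g C cm^-3) = bulk density (g cm^-3) x OC mass fraction.

    ``oc_fraction`` is unitless in [0, 1]; values above 1 are rejected to
    guard against percent/fraction confusion.
    """
    bd = np.asarray(bulk_density, dtype=float)
    ocf = np.asarray(oc_fraction, dtype=float)
    if (bd < 0).any() or (ocf < 0).any():
        raise ValueError("bulk_density and oc_fraction must be non-negative")
    if (ocf > 1).any():
        raise ValueError("oc_fraction must be <= 1 (got a value > 1; percent instead of fraction?)")
    out = bd * ocf
    return float(out) if out.ndim == 0 else out


def extract_covariates(cores: pd.DataFrame, grid: CovariateGrid) -> TrainingMatrix:
    """Attach nearest-pixel covariate values to every depth sample.

    Cores outside the grid extent raise with the offending location ids;
    cores on nodata (off-mask) pixels are dropped with a logged count.
    """
    s = grid.spec
    out_of_bounds = (
        (cores["lon"] < s.lon_min)
        | (cores["lon"] > s.lon_max)
        | (cores["lat"] < s.lat_min)
        | (cores["lat"] > s.lat_max)
    )
    if out_of_bounds.any():
        bad = sorted(cores.loc[out_of_bounds, "location_id"].unique())
        raise ValueError(f"core location(s) outside grid bounds: {bad}")

    values = grid.values_at(cores["lon"].to_numpy(), cores["lat"].to_numpy())
    values.index = cores.index
    joined = pd.concat([cores, values], axis=1)
    complete = values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("extract_covariates: dropped %d sample(s) on nodata pixels", n_dropped)
    data = joined.loc[complete].reset_index(drop=True)
    return TrainingMatrix(
        data=data, covariate_names=grid.names, categorical=grid.categorical
    )


def collinearity_screen(
    matrix: TrainingMatrix, threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Pearson correlation among continuous covariates (advisory).

    Returns one row per unordered pair with columns ``var_a, var_b, r,
    flagged``; pairs with |r| > threshold are flagged but nothing is
    dropped (the screen reports, the analyst decides). Constant columns
    yield ``r = NaN`` with ``flagged = False`` and a ``note``.
    """
    cont = [n for n in matrix.covariate_names if n not in matrix.categorical]
    if len(cont) < 2:
        raise ValueError("need at least two continuous covariates")
    rows = []
    for i, a in enumerate(cont):
        for b in cont[i + 1 :]:
            xa, xb = matrix.data[a].to_numpy(), matrix.data[b].to_numpy()
            if xa.std() == 0 or xb.std() == 0:
                rows.append({"var_a": a, "var_b": b, "r": np.nan, "flagged": False,
                             "note": "undefined (constant column)"})
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({"var_a": a, "var_b": b, "r": r,
                         "flagged": bool(abs(r) > threshold), "note": ""})
    return pd.DataFrame(rows)


def coverage_report(
    matrix: TrainingMatrix,
    grid: CovariateGrid,
    n_background: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare training covariate distributions against the mapped extent.

    Draws ``n_background`` random points from the marsh mask and, per
    continuous covariate, reports background vs training quantiles and the
    two-sample Kolmogorov–Smirnov statistic. Large KS values indicate
    covariate ranges the training data do not represent.
    """
    rows_idx, cols_idx = grid.masked_indices()
    if rows_idx.size == 0:
        raise ValueError("grid mask is empty")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows_idx.size, size=n_background, replace=rows_idx.size < n_background)

    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    out = []
    for name in grid.continuous_names:
        bg = grid.covariates[name][rows_idx[pick], cols_idx[pick]]
        tr = matrix.data[name].to_numpy()
        ks = stats.ks_2samp(tr, bg)
        rec = {"covariate": name, "ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}
        for q in qs:
            rec[f"train_q{int(q * 100):02d}"] = float(np.quantile(tr, q))
            rec[f"background_q{int(q * 100):02d}"] = float(np.quantile(bg, q))
        out.append(rec)
    return pd.DataFrame(out)
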