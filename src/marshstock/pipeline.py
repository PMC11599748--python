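"""End-to-end orchestration: simulate -> train -> uncertainty -> stocks -> aggregate.

A single :class:`RunConfig` (loadable from YAML) plus the input files
determine every output bit-for-bit. Stages write their products under the
output directory and record them in a manifest (paths, SHA-256 hashes,
config echo, package versions); a rerun with ``resume=True`` skips stages
whose outputs already exist, so deleting one stage's outputs regenerates
only that stage and those after it.

All randomness flows from one top-level seed through named per-stage
substreams (`numpy.random.SeedSequence` children), so stages stay
reproducible even when earlier stages are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from marshstock import fileio
from marshstock.aggregation import aggregate_cells, bivariate_classify, summarize_regions
from marshstock.grids import CovariateGrid, GridSpec
from marshstock.model import ModelSpec, fit, tune
from marshstock.spatial_cv import (
    cross_validate,
    knndm_folds,
    random_folds,
    sample_prediction_points,
)
from marshstock.stocks import STANDARD_LAYERS, apply_aoa, predict_layer_stocks
from marshstock.synthetic import (
    GenerativeOCDParams,
    SamplingDesign,
    generate_covariate_grid,
    generate_true_ocd,
    sample_cores,
)
from marshstock.training import extract_covariates, filter_sites
from marshstock.uncertainty import (
    aoa_mask,
    aoa_threshold,
    build_space,
    calibrate_error,
    expected_error_surface,
    pixel_di,
    training_di,
)

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "folds", "cv", "train", "uncertainty", "stocks", "aggregate")


def _substream_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the top-level seed."""
    idx = _STAGE_NAMES.index(stage)
    child = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serializable to YAML."""

    out_dir: str = "marshstock_run"
    seed: int = 0

    # synthetic landscape
    grid: dict = field(default_factory=lambda: {
        "lon_min": 0.0, "lon_max": 1.0, "lat_min": 50.0, "lat_max": 51.0,
        "resolution": 0.01,
    })
    covariate_names: list[str] = field(default_factory=lambda: [
        "elevation", "ndvi_median", "ndvi_stdev", "slope", "tidal_amplitude",
        "tsm", "temp_max", "temp_min", "precip_max", "precip_min", "pet_driest",
        "sealevel_class",
    ])
    categorical: dict = field(default_factory=lambda: {"coastal_type": 4})
    smoothness: float = 0.05
    mask_fraction: float = 0.5
    truth: dict = field(default_factory=lambda: {
        "intercept": 0.03,
        "covariate_effects": {"elevation": -0.008, "ndvi_median": 0.005,
                              "tidal_amplitude": 0.003},
        "depth_effect": -0.00005,
        "noise_sd": 0.004,
    })
    design: dict = field(default_factory=lambda: {
        "n_locations": 300, "n_clusters": 3, "cluster_fraction": 0.85,
        "cluster_sd": 0.05, "depth_grid": [5.0, 15.0, 25.0, 45.0, 65.0, 90.0],
        "deep_retention": 0.5,
    })

    # CV / model
    cv_k: int = 5
    cv_strategy: str = "knndm"  # or "random"
    n_prediction_points: int = 5000
    model: dict = field(default_factory=lambda: {"mtry": 3, "min_node": 5, "n_trees": 300})
    tune: bool = False
    tuning_grid: dict | None = None

    # uncertainty / aggregation
    window_fraction: float = 0.1
    min_window: int = 20
    cell_size: float = 2.0
    layers: list = field(default_factory=lambda: [[0.0, 30.0], [30.0, 100.0]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path, include_out_dir: bool = True) -> None:
        doc = dataclasses.asdict(self)
        if not include_out_dir:
            # the output location is not a scientific input; omitting it keeps
            # the config echo (and hence the manifest) location-independent
            doc.pop("out_dir")
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    def grid_spec(self) -> GridSpec:
        return GridSpec(seed=_substream_seed(self.seed, "simulate"), **self.grid)

    def truth_params(self) -> GenerativeOCDParams:
        return GenerativeOCDParams(**self.truth)

    def sampling_design(self) -> SamplingDesign:
        d = dict(self.design)
        d["depth_grid"] = tuple(d.get("depth_grid", (5.0, 15.0, 25.0, 45.0, 65.0, 90.0)))
        return SamplingDesign(seed=_substream_seed(self.seed, "simulate") + 1, **d)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(seed=_substream_seed(self.seed, "train"), **self.model)

    def layer_tuples(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(a), float(b)) for a, b in self.layers)


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def simulate_stage(config: RunConfig, out: Path) -> dict[str, Path]:
    """Generate covariates, truth rasters and the clustered core table."""
    spec = config.grid_spec()
    grid = generate_covariate_grid(
        spec, config.covariate_names, config.smoothness,
        categorical=config.categorical, mask_fraction=config.mask_fraction,
    )
    params = config.truth_params()
    cores = sample_cores(grid, params, config.sampling_design())

    paths = {
        "grid": fileio.write_grid(out / "covariates.tif", grid),
        "cores": fileio.write_cores(out / "cores.csv", cores),
    }
    depths = sorted({d for layer in config.layer_tuples() for d in layer})
    truth_bands = {f"ocd_truth_{d:g}cm": generate_true_ocd(grid, params, d) for d in depths}
    paths["truth"] = fileio.write_raster(
        out / "ocd_truth.tif", truth_bands, spec, units="g C cm^-3"
    )
    return paths


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Stage order: simulate (synthetic inputs) -> training table -> folds ->
    CV -> model fit -> DI/AOA/expected error -> layer stocks -> aggregation.
    On ``resume``, stages whose output files all exist are skipped and
    their products are re-read from disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml", include_out_dir=False)

    # -- simulate ----------------------------------------------------------
    sim_paths = [out / "covariates.tif", out / "cores.csv", out / "ocd_truth.tif"]
    if not (resume and _stage_done(sim_paths)):
        logger.info("stage simulate")
        simulate_stage(config, out)
    grid = fileio.read_grid(out / "covariates.tif")
    cores = fileio.read_cores(out / "cores.csv")

    # -- training table ----------------------------------------------------
    cores = filter_sites(cores, mask_grid=None)
    matrix = extract_covariates(cores, grid)
    locations = matrix.locations()

    # -- folds -------------------------------------------------------------
    folds_path = out / "folds.csv"
    seed_folds = _substream_seed(config.seed, "folds")
    pred_points = sample_prediction_points(
        grid, n=config.n_prediction_points, seed=seed_folds
    )
    if not (resume and folds_path.exists()):
        logger.info("stage folds (%s)", config.cv_strategy)
        if config.cv_strategy == "knndm":
            folds = knndm_folds(locations, pred_points, k=config.cv_k, seed=seed_folds)
        elif config.cv_strategy == "random":
            folds = random_folds(locations, k=config.cv_k, seed=seed_folds)
        else:
            raise ValueError(f"unknown cv_strategy: {config.cv_strategy!r}")
        frame = folds.to_frame()
        frame.attrs = {}
        frame.to_csv(folds_path, index=False)
        (out / "folds.json").write_text(json.dumps(
            {"k": folds.k, "strategy": folds.strategy, "quality": folds.quality}
        ))
    fold_frame = pd.read_csv(folds_path)
    fold_meta = json.loads((out / "folds.json").read_text())
    from marshstock.spatial_cv import FoldAssignment  # local to keep imports tidy

    folds = FoldAssignment(
        folds=pd.Series(fold_frame["fold"].to_numpy(), index=fold_frame["location_id"]),
        k=int(fold_meta["k"]), quality=float(fold_meta["quality"]),
        strategy=fold_meta["strategy"],
    )

    # -- optional tuning + CV ---------------------------------------------
    spec = config.model_spec()
    if config.tune:
        logger.info("stage tune")
        table, spec = tune(matrix, folds, grid=config.tuning_grid,
                           base_seed=_substream_seed(config.seed, "train"))
        table.to_csv(out / "tuning.csv", index=False)
    cv_path = out / "cv_samples.csv"
    if not (resume and cv_path.exists() and (out / "cv_metrics.json").exists()):
        logger.info("stage cv")
        cv = cross_validate(matrix, folds, spec)
        cv.samples.to_csv(cv_path, index=False)
        (out / "cv_metrics.json").write_text(json.dumps(
            {"r2": cv.r2, "rmse": cv.rmse, "k": cv.k, "strategy": cv.strategy}
        ))
    from marshstock.spatial_cv import CVResult

    cv_samples = pd.read_csv(cv_path)
    cv_meta = json.loads((out / "cv_metrics.json").read_text())
    cv = CVResult(samples=cv_samples, r2=cv_meta["r2"], rmse=cv_meta["rmse"],
                  k=cv_meta["k"], strategy=cv_meta["strategy"])

    # -- final model -------------------------------------------------------
    model_path = out / "model.pkl"
    if not (resume and model_path.exists()):
        logger.info("stage train")
        fitted = fit(matrix, spec)
        fileio.write_model(model_path, fitted)
    fitted = fileio.read_model(model_path)

    # -- uncertainty: DI, AOA, error calibration ---------------------------
    layers = config.layer_tuples()
    depths = sorted({d for layer in layers for d in layer})
    unc_paths = [out / "di.tif", out / "aoa.tif", out / "expected_error.tif",
                 out / "aoa_threshold.json"]
    if not (resume and _stage_done(unc_paths)):
        logger.info("stage uncertainty")
        space = build_space(fitted, matrix)
        # CV residuals and training DI must align by sample; re-order the
        # residuals to the matrix row order before calibration.
        tdi = training_di(matrix, space, folds)
        key = ["location_id", "depth_cm"]
        aligned = matrix.data[key].merge(
            cv.samples[key + ["residual"]], on=key, how="left"
        )
        cv_aligned = CVResult(
            samples=aligned.rename(columns={"residual": "residual"}),
            r2=cv.r2, rmse=cv.rmse, k=cv.k, strategy=cv.strategy,
        )
        error_model = calibrate_error(
            cv_aligned, tdi,
            window_fraction=config.window_fraction, min_window=config.min_window,
        )
        threshold = aoa_threshold(tdi)

        di_rasters = {d: pixel_di(grid, space, matrix, d) for d in depths}
        aoa_bands, err_bands = {}, {}
        for layer in layers:
            name = f"{layer[0]:g}_{layer[1]:g}"
            mask_prod = aoa_mask(di_rasters, threshold, layer)
            aoa_bands[f"aoa_average_{name}"] = mask_prod["average"]
            aoa_bands[f"aoa_inside_{name}"] = mask_prod["inside"].astype(float)
            surf = expected_error_surface(
                grid, space, matrix, error_model, layer, di_at_depths=di_rasters
            )
            err_bands[f"expected_error_{name}"] = surf["error"]
        fileio.write_raster(out / "di.tif",
                            {f"di_{d:g}cm": r for d, r in di_rasters.items()},
                            grid.spec, units="unitless")
        fileio.write_raster(out / "aoa.tif", aoa_bands, grid.spec)
        fileio.write_raster(out / "expected_error.tif", err_bands, grid.spec,
                            units="Mg C ha^-1")
        (out / "aoa_threshold.json").write_text(json.dumps(
            {"threshold": threshold, "n_training_di": len(tdi),
             "calibration_window": error_model.window}
        ))
    aoa_bands, _, _ = fileio.read_raster(out / "aoa.tif")
    err_bands, _, _ = fileio.read_raster(out / "expected_error.tif")

    # -- stocks ------------------------------------------------------------
    stock_paths = [out / "stocks_premask.tif", out / "stocks.tif"]
    if not (resume and _stage_done(stock_paths)):
        logger.info("stage stocks")
        premask = predict_layer_stocks(fitted, grid, layers=layers)
        for layer in layers:
            name = f"{layer[0]:g}_{layer[1]:g}"
            premask.error[layer] = err_bands[f"expected_error_{name}"]
        aoa_inside = {
            layer: aoa_bands[f"aoa_inside_{layer[0]:g}_{layer[1]:g}"] > 0.5
            for layer in layers
        }
        final = apply_aoa(premask, aoa_inside)
        fileio.write_raster(
            out / "stocks_premask.tif",
            {f"stock_{layer[0]:g}_{layer[1]:g}": premask.stock[layer] for layer in layers},
            grid.spec, units="Mg C ha^-1",
        )
        final_bands = {}
        for layer in layers:
            name = f"{layer[0]:g}_{layer[1]:g}"
            final_bands[f"stock_{name}"] = final.stock[layer]
            final_bands[f"error_{name}"] = final.error[layer]
        fileio.write_raster(out / "stocks.tif", final_bands, grid.spec,
                            units="Mg C ha^-1")

    # -- aggregation -------------------------------------------------------
    agg_paths = [out / "cells.csv", out / "regions.csv", out / "cells.geojson",
                 out / "cells_bivariate.csv"]
    if not (resume and _stage_done(agg_paths)):
        logger.info("stage aggregate")
        final = _reload_stock_map(out, grid, layers)
        cells = aggregate_cells(final, cell_size=config.cell_size)
        cells.to_csv(out / "cells.csv", index=False)
        fileio.cells_to_geojson(cells, out / "cells.geojson", cell_size=config.cell_size)

        cells_pre = aggregate_cells(final, cell_size=config.cell_size, use_premask=True)
        name0 = f"{layers[0][0]:g}_{layers[0][1]:g}"
        biv = bivariate_classify(cells_pre, f"mean_stock_{name0}", f"mean_error_{name0}")
        biv.to_csv(out / "cells_bivariate.csv", index=False)

        region_raster = _region_raster_from_cores(grid, cores)
        regions = summarize_regions(final, region_raster)
        regions.to_csv(out / "regions.csv", index=False)

    # -- manifest ----------------------------------------------------------
    products = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {p.name: fileio.sha256_of(p) for p in products},
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _reload_stock_map(out: Path, grid: CovariateGrid, layers):
    """Rebuild the final LayerStockMap from the stage outputs on disk."""
    from marshstock.stocks import LayerStockMap

    premask_bands, _, _ = fileio.read_raster(out / "stocks_premask.tif")
    final_bands, _, _ = fileio.read_raster(out / "stocks.tif")
    aoa_bands, _, _ = fileio.read_raster(out / "aoa.tif")
    stock, error, aoa_inside, pre_stock = {}, {}, {}, {}
    for layer in layers:
        name = f"{layer[0]:g}_{layer[1]:g}"
        stock[layer] = final_bands[f"stock_{name}"]
        error[layer] = final_bands[f"error_{name}"]
        aoa_inside[layer] = aoa_bands[f"aoa_inside_{name}"] > 0.5
        pre_stock[layer] = premask_bands[f"stock_{name}"]
    premask_err, _, _ = fileio.read_raster(out / "expected_error.tif")
    premask = LayerStockMap(
        grid=grid, stock=pre_stock,
        error={layer: premask_err[f"expected_error_{layer[0]:g}_{layer[1]:g}"]
               for layer in layers},
    )
    return LayerStockMap(grid=grid, stock=stock, error=error,
                         aoa_inside=aoa_inside, premask=premask)


def _region_raster_from_cores(grid: CovariateGrid, cores: pd.DataFrame) -> np.ndarray:
    """Region-label raster: each masked pixel takes the label of its nearest core cluster.

    The synthetic cluster labels stand in for country/realm geometries; a
    pixel is labelled by the region of the geographically nearest core.
    """
    from marshstock.spatial_cv import _pairwise_km

    locs = cores.groupby("location_id")[["lon", "lat", "region"]].first()
    rows_idx, cols_idx = grid.masked_indices()
    d = _pairwise_km(grid.lon[cols_idx], grid.lat[rows_idx],
                     locs["lon"].to_numpy(), locs["lat"].to_numpy())
    nearest = locs["region"].to_numpy()[d.argmin(axis=1)]
    raster = np.full(grid.shape, None, dtype=object)
    raster[rows_idx, cols_idx] = nearest
    return raster


def _versions() -> dict[str, str]:
    import sklearn

    import marshstock

    return {
        "marshstock": marshstock.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
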