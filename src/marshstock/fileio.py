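"""Raster and table I/O.

Rasters are written as multi-band float64 TIFFs via ``tifffile`` with a
JSON sidecar (``<name>.tif`` + ``<name>.tif.json``) carrying the
georeferencing: WGS84 bounds, resolution, band names, per-band nodata and
the categorical flags. NaN is the in-memory nodata sentinel and round-trips
bit-exactly through the float TIFF. Core tables and summary tables are
plain CSV with pinned schemas.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from marshstock.grids import CovariateGrid, GridSpec
from marshstock.training import CORE_COLUMNS

CRS = "EPSG:4326"


def write_raster(
    path: str | Path,
    bands: dict[str, np.ndarray],
    spec: GridSpec,
    categorical: frozenset[str] = frozenset(),
    units: str | None = None,
) -> Path:
    """Write named 2-D bands to ``path`` (.tif) with a JSON georeferencing sidecar."""
    path = Path(path)
    names = list(bands)
    stack = np.stack([np.asarray(bands[n], dtype=np.float64) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "crs": CRS,
        "lon_min": spec.lon_min,
        "lon_max": spec.lon_max,
        "lat_min": spec.lat_min,
        "lat_max": spec.lat_max,
        "resolution": spec.resolution,
        "seed": spec.seed,
        "bands": names,
        "categorical": sorted(categorical),
        "nodata": "nan",
        "units": units,
        "registration": "pixel-centre, row-major from the north-west corner",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path) -> tuple[dict[str, np.ndarray], GridSpec, frozenset]:
    """Read a raster written by :func:`write_raster`.

    Returns (bands, spec, categorical names). Raises if the sidecar is
    missing or its CRS differs from WGS84.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing georeferencing sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta["crs"] != CRS:
        raise ValueError(f"CRS mismatch in {path}: {meta['crs']} != {CRS}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    spec = GridSpec(
        lon_min=meta["lon_min"],
        lon_max=meta["lon_max"],
        lat_min=meta["lat_min"],
        lat_max=meta["lat_max"],
        resolution=meta["resolution"],
        seed=meta.get("seed", 0),
    )
    bands = {name: stack[i] for i, name in enumerate(meta["bands"])}
    return bands, spec, frozenset(meta.get("categorical", []))


def write_grid(path: str | Path, grid: CovariateGrid) -> Path:
    """Serialize a covariate grid (covariates + mask band) to TIFF + sidecar."""
    bands = dict(grid.covariates)
    bands["__mask__"] = grid.mask.astype(np.float64)
    return write_raster(path, bands, grid.spec, categorical=grid.categorical)


def read_grid(path: str | Path) -> CovariateGrid:
    bands, spec, categorical = read_raster(path)
    mask = bands.pop("__mask__") > 0.5
    return CovariateGrid(spec=spec, covariates=bands, mask=mask, categorical=categorical)


def write_cores(path: str | Path, cores: pd.DataFrame) -> Path:
    path = Path(path)
    _check_schema(cores, CORE_COLUMNS, str(path))
    cores[CORE_COLUMNS].to_csv(path, index=False)
    return path


def read_cores(path: str | Path) -> pd.DataFrame:
    cores = pd.read_csv(path)
    _check_schema(cores, CORE_COLUMNS, str(path))
    return cores


def _check_schema(frame: pd.DataFrame, columns: list[str], context: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{context}: missing required column(s) {missing}")


def write_model(path: str | Path, fitted) -> Path:
    """Persist a fitted model (pickle) with a JSON sidecar of its metadata."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(fitted, fh)
    sidecar = {
        "spec": {
            "mtry": fitted.spec.mtry,
            "min_node": fitted.spec.min_node,
            "n_trees": fitted.spec.n_trees,
            "importance_mode": fitted.spec.importance_mode,
            "bootstrap": fitted.spec.bootstrap,
            "seed": fitted.spec.seed,
        },
        "predictor_names": fitted.predictor_names,
        "raw_predictor_names": fitted.raw_predictor_names,
        "n_samples": fitted.n_samples,
        "importance": dict(zip(fitted.predictor_names, fitted.importance.tolist())),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_model(path: str | Path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def cells_to_geojson(cell_table: pd.DataFrame, path: str | Path, cell_size: float = 2.0) -> Path:
    """Write the 2°-cell table as a GeoJSON FeatureCollection of cell polygons."""
    features = []
    for _, row in cell_table.iterrows():
        ring = [
            [row["lon_min"], row["lat_min"]],
            [row["lon_max"], row["lat_min"]],
            [row["lon_max"], row["lat_max"]],
            [row["lon_min"], row["lat_max"]],
            [row["lon_min"], row["lat_min"]],
        ]
        props = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in row.items()
        }
        features.append(
            {"type": "Feature", "geometry": {"type": "Polygon", "coordinates": [ring]},
             "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path
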