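"""Regular lon/lat raster grids of named covariates with a marsh mask.

Conventions (used everywhere in the package):

* coordinates are WGS84 decimal degrees, pixel registration is centre-based;
* arrays are row-major from the north-west corner, i.e. row 0 holds the
  northernmost pixels and ``lat`` is strictly decreasing;
* pixel area (ha) is computed at the pixel centre as
  ``(111.32 km * res) * (111.32 km * res * cos(lat)) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KM_PER_DEGREE = 111.32  # metres per degree of latitude / equatorial longitude


def pixel_area_ha(lat: np.ndarray, resolution: float) -> np.ndarray:
    """Area (hectares) of a square pixel of side ``resolution`` degrees at latitude ``lat``.

    One km^2 is 100 ha; the meridional side is constant, the zonal side
    shrinks with cos(latitude).
    """
    lat = np.asarray(lat, dtype=float)
    side_ns = KM_PER_DEGREE * resolution
    side_ew = KM_PER_DEGREE * resolution * np.cos(np.deg2rad(lat))
    return side_ns * side_ew * 100.0


@dataclass(frozen=True)
class GridSpec:
    """Extent, resolution and seed of a synthetic raster grid.

    Latitudes are restricted to the 60° S – 60° N band in which tidal-marsh
    covariate data exist.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lon_max > self.lon_min:
            raise ValueError("lon_max must exceed lon_min")
        if not self.lat_max > self.lat_min:
            raise ValueError("lat_max must exceed lat_min")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if max(abs(self.lat_min), abs(self.lat_max)) > 60:
            raise ValueError("latitudes must lie within 60° S – 60° N")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    def lon_centres(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    def lat_centres(self) -> np.ndarray:
        """Pixel-centre latitudes, north to south (row-major from NW corner)."""
        return self.lat_max - self.resolution * (np.arange(self.n_lat) + 0.5)


@dataclass
class CovariateGrid:
    """A stack of named covariate rasters over a boolean marsh mask.

    ``covariates`` maps name -> 2-D float array of shape (n_lat, n_lon);
    categorical covariates hold integer class codes stored as floats.
    """

    spec: GridSpec
    covariates: dict[str, np.ndarray]
    mask: np.ndarray
    categorical: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        shape = (self.spec.n_lat, self.spec.n_lon)
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} != grid shape {shape}")
        for name, arr in self.covariates.items():
            if arr.shape != shape:
                raise ValueError(f"covariate {name!r} shape {arr.shape} != {shape}")
        unknown = self.categorical - set(self.covariates)
        if unknown:
            raise ValueError(f"categorical names not in covariates: {sorted(unknown)}")
        if not self.mask.any():
            raise ValueError("empty grid: marsh mask contains no pixels")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.spec.n_lat, self.spec.n_lon)

    @property
    def names(self) -> list[str]:
        return list(self.covariates)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.covariates if n not in self.categorical]

    @property
    def lon(self) -> np.ndarray:
        return self.spec.lon_centres()

    @property
    def lat(self) -> np.ndarray:
        return self.spec.lat_centres()

    @property
    def area_ha(self) -> np.ndarray:
        """Per-pixel area in hectares, broadcast over the full grid."""
        per_row = pixel_area_ha(self.lat, self.spec.resolution)
        return np.broadcast_to(per_row[:, None], self.shape).copy()

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel (row, col) indices for coordinates inside the grid bounds.

        Raises ``ValueError`` for coordinates outside the extent.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        s = self.spec
        out = (
            (lon < s.lon_min) | (lon > s.lon_max) | (lat < s.lat_min) | (lat > s.lat_max)
        )
        if out.any():
            raise ValueError(f"{int(out.sum())} coordinate(s) outside grid bounds")
        col = np.clip(((lon - s.lon_min) / s.resolution).astype(int), 0, s.n_lon - 1)
        row = np.clip(((s.lat_max - lat) / s.resolution).astype(int), 0, s.n_lat - 1)
        return row, col

    def masked_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) arrays of the pixels on the marsh mask."""
        return np.nonzero(self.mask)

    def masked_centres(self) -> pd.DataFrame:
        """lon/lat of every masked pixel centre (row-major order)."""
        rows, cols = self.masked_indices()
        return pd.DataFrame({"lon": self.lon[cols], "lat": self.lat[rows]})

    def masked_table(self) -> pd.DataFrame:
        """Covariate values at every masked pixel, one row per pixel.

        Row order matches :meth:`masked_centres` and :meth:`masked_indices`.
        """
        rows, cols = self.masked_indices()
        data = {name: arr[rows, cols] for name, arr in self.covariates.items()}
        return pd.DataFrame(data)

    def values_at(self, lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
        """Nearest-pixel covariate values at the given coordinates.

        Off-mask pixels yield NaN rows (callers decide whether to drop).
        """
        row, col = self.index_of(lon, lat)
        on_mask = self.mask[row, col]
        data = {}
        for name, arr in self.covariates.items():
            vals = arr[row, col].astype(float)
            vals[~on_mask] = np.nan
            data[name] = vals
        return pd.DataFrame(data)

    def new_raster(self, fill: float = np.nan) -> np.ndarray:
        return np.full(self.shape, fill, dtype=float)
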