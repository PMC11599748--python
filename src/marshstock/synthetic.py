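"""Synthetic marsh landscapes: covariate fields, a known OCD truth, clustered cores.

The generator emulates the salient features of the real training data:
strong geographic clustering of core locations (a few national clusters
holding most of the data), depth-stratified sampling with fewer deep
samples, spatially autocorrelated covariates over a marsh mask, and a known
generative OCD(x, y, d) so that every downstream stage can be checked
against ground truth.

Covariate fields are produced by smoothing white noise with a Gaussian
kernel whose correlation length is given in degrees; this is simple,
seedable, and sufficient to create the train/prediction distribution shift
that the area-of-applicability machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from marshstock.grids import CovariateGrid, GridSpec


@dataclass(frozen=True)
class GenerativeOCDParams:
    """Parameters of the linear-additive generative OCD model.

    OCD(x, y, d) = intercept + sum_j effect_j * covariate_j(x, y)
                   + depth_effect * d,   clipped at 0.

    Units: intercept and noise_sd in g C cm^-3; depth_effect per cm.
    A near-zero ``depth_effect`` reproduces the roughly depth-stable carbon
    density profiles typical of marsh soils.
    """

    intercept: float = 0.03
    covariate_effects: dict[str, float] = field(default_factory=dict)
    depth_effect: float = -0.00005
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SamplingDesign:
    """Clustered, depth-stratified core sampling design.

    ``cluster_fraction`` of locations are drawn from ``n_clusters`` Gaussian
    clusters of spread ``cluster_sd`` degrees; the remainder are uniform over
    the marsh mask. Each location is sampled at every depth in ``depth_grid``
    (layer-centre depths, cm); samples deeper than 30 cm are retained with
    probability ``deep_retention`` — mirroring the sparser deep layer of the
    real data (roughly a third of all samples).
    """

    n_locations: int = 300
    n_clusters: int = 3
    cluster_fraction: float = 0.85
    cluster_sd: float = 0.05
    depth_grid: tuple[float, ...] = (5.0, 15.0, 25.0, 45.0, 65.0, 90.0)
    deep_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if not 0 < self.deep_retention <= 1:
            raise ValueError("deep_retention must be in (0, 1]")
        if any(d <= 0 for d in self.depth_grid):
            raise ValueError("all depths must be positive")
        if self.n_locations < self.n_clusters:
            raise ValueError("n_locations must be >= n_clusters")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel of ``sigma_px`` pixels."""
    noise = rng.standard_normal(shape)
    if sigma_px <= 0:
        return noise
    return gaussian_filter(noise, sigma=sigma_px, mode="reflect")


def generate_covariate_grid(
    spec: GridSpec,
    names: list[str],
    smoothness: float,
    categorical: dict[str, int] | None = None,
    mask_fraction: float = 0.6,
) -> CovariateGrid:
    """Generate spatially autocorrelated covariates over a random marsh mask.

    Parameters
    ----------
    spec:
        Grid extent/resolution/seed.
    names:
        Continuous covariate names; each becomes an independent smoothed
        field standardized to mean 0 / sd 1 over the mask.
    smoothness:
        Correlation length in degrees (Gaussian kernel sigma).
    categorical:
        Optional mapping name -> number of classes; each becomes a smoothed
        field quantile-binned into integer class codes.
    mask_fraction:
        Fraction of pixels inside the marsh mask (mask itself is a smoothed
        field thresholded at this quantile, so it is spatially coherent).
    """
    if not names:
        raise ValueError("names must be non-empty")
    if not smoothness >= 0:
        raise ValueError("smoothness must be >= 0")
    if not 0 < mask_fraction <= 1:
        raise ValueError("mask_fraction must be in (0, 1]")
    categorical = categorical or {}

    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_lat, spec.n_lon)
    sigma_px = smoothness / spec.resolution

    mask_field = _smooth_field(rng, shape, max(sigma_px, 1.0))
    threshold = np.quantile(mask_field, 1.0 - mask_fraction)
    mask = mask_field >= threshold
    if not mask.any():
        raise ValueError("empty grid after masking")

    covariates: dict[str, np.ndarray] = {}
    for name in names:
        fld = _smooth_field(rng, shape, sigma_px)
        mu, sd = fld[mask].mean(), fld[mask].std()
        covariates[name] = (fld - mu) / sd if sd > 0 else fld - mu

    for name, n_classes in categorical.items():
        fld = _smooth_field(rng, shape, max(sigma_px, 1.0))
        edges = np.quantile(fld, np.linspace(0, 1, n_classes + 1)[1:-1])
        covariates[name] = np.digitize(fld, edges).astype(float)

    return CovariateGrid(
        spec=spec,
        covariates=covariates,
        mask=mask,
        categorical=frozenset(categorical),
    )


def generate_true_ocd(grid: CovariateGrid, params: GenerativeOCDParams, depth: float) -> np.ndarray:
    """Noise-free generative OCD raster (g C cm^-3) at one depth.

    NaN outside the marsh mask; values clipped at the physical floor of 0.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    unknown = set(params.covariate_effects) - set(grid.covariates)
    if unknown:
        raise ValueError(f"unknown covariate name(s) in effects: {sorted(unknown)}")

    ocd = np.full(grid.shape, params.intercept + params.depth_effect * depth, dtype=float)
    for name, coef in params.covariate_effects.items():
        ocd += coef * grid.covariates[name]
    ocd = np.clip(ocd, 0.0, None)
    ocd[~grid.mask] = np.nan
    return ocd


def true_layer_stock(
    grid: CovariateGrid, params: GenerativeOCDParams, layer: tuple[float, float]
) -> np.ndarray:
    """Ground-truth layer stock raster (Mg C ha^-1) by the same trapezoid used downstream."""
    top, bottom = layer
    ocd_top = generate_true_ocd(grid, params, top)
    ocd_bot = generate_true_ocd(grid, params, bottom)
    return (ocd_top + ocd_bot) / 2.0 * (bottom - top) * 100.0


def _place_clustered_locations(
    rng: np.random.Generator, grid: CovariateGrid, design: SamplingDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw core locations; returns (lon, lat, cluster_id) with -1 = scattered."""
    centres = grid.masked_centres()
    if len(centres) < design.n_clusters:
        raise ValueError("mask too small to place clusters")

    centre_idx = rng.choice(len(centres), size=design.n_clusters, replace=False)
    c_lon = centres["lon"].to_numpy()[centre_idx]
    c_lat = centres["lat"].to_numpy()[centre_idx]

    n_clustered = int(round(design.n_locations * design.cluster_fraction))
    lons, lats, labels = [], [], []

    assignment = rng.integers(0, design.n_clusters, size=n_clustered)
    for i in range(n_clustered):
        c = int(assignment[i])
        # rejection-sample until the jittered point falls on the mask
        for _ in range(1000):
            lon = c_lon[c] + rng.normal(0, design.cluster_sd)
            lat = c_lat[c] + rng.normal(0, design.cluster_sd)
            try:
                row, col = grid.index_of(lon, lat)
            except ValueError:
                continue
            if grid.mask[row[0], col[0]]:
                break
        else:
            raise ValueError("mask too small to place clusters")
        lons.append(lon)
        lats.append(lat)
        labels.append(c)

    n_scattered = design.n_locations - n_clustered
    if n_scattered > 0:
        idx = rng.choice(len(centres), size=n_scattered, replace=True)
        jitter = grid.spec.resolution / 2
        lons.extend(centres["lon"].to_numpy()[idx] + rng.uniform(-jitter, jitter, n_scattered))
        lats.extend(centres["lat"].to_numpy()[idx] + rng.uniform(-jitter, jitter, n_scattered))
        labels.extend([-1] * n_scattered)

    return np.array(lons), np.array(lats), np.array(labels)


def sample_cores(
    grid: CovariateGrid,
    truth_params: GenerativeOCDParams,
    design: SamplingDesign,
) -> pd.DataFrame:
    """Sample depth-resolved cores from the generative truth.

    Returns the canonical core table with columns
    ``location_id, lon, lat, depth_cm, ocd_gcm3, region``; the cluster label
    doubles as the country/realm stand-in (``cluster_<i>`` or ``scattered``).
    Observed OCD = truth at the location's nearest pixel + N(0, noise_sd),
    clipped at 0.
    """
    rng = np.random.default_rng(design.seed)
    lon, lat, cluster = _place_clustered_locations(rng, grid, design)
    row, col = grid.index_of(lon, lat)

    records = []
    for i in range(design.n_locations):
        base = truth_params.intercept
        for name, coef in truth_params.covariate_effects.items():
            base += coef * grid.covariates[name][row[i], col[i]]
        region = f"cluster_{cluster[i]}" if cluster[i] >= 0 else "scattered"
        for depth in design.depth_grid:
            if depth > 30 and rng.random() > design.deep_retention:
                continue
            truth = max(base + truth_params.depth_effect * depth, 0.0)
            obs = truth + (rng.normal(0, truth_params.noise_sd) if truth_params.noise_sd else 0.0)
            records.append(
                {
                    "location_id": f"loc_{i:05d}",
                    "lon": lon[i],
                    "lat": lat[i],
                    "depth_cm": float(depth),
                    "ocd_gcm3": max(obs, 0.0),
                    "region": region,
                }
            )
    return pd.DataFrame.from_records(records)
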