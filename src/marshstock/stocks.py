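"""Per-pixel layer stocks: standard-depth OCD prediction and trapezoidal integration.

A layer stock (Mg C ha^-1) is the mean of the OCD predictions at the
layer's top and bottom depths times the layer thickness in cm times 100.
The x100 factor is the unit conversion g C cm^-3 * cm -> Mg C ha^-1
(1 g cm^-2 = 100 Mg ha^-1) and is applied here, once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from marshstock.grids import CovariateGrid
from marshstock.model import FittedModel, predict_ocd

STANDARD_LAYERS: tuple[tuple[float, float], ...] = ((0.0, 30.0), (30.0, 100.0))


def integrate_stock(ocd_top, ocd_bottom, thickness: float):
    """Trapezoidal layer stock (Mg C ha^-1) from boundary OCDs (g C cm^-3).

    stock = ((ocd_top + ocd_bottom) / 2) * thickness_cm * 100.
    Unit audit: g C cm^-3 x cm = g C cm^-2; 1 g C cm^-2 over a hectare
    (1e8 cm^2) is 1e8 g = 100 Mg, hence the factor 100.
    """
    top = np.asarray(ocd_top, dtype=float)
    bottom = np.asarray(ocd_bottom, dtype=float)
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if np.nanmin(top, initial=0.0) < 0 or np.nanmin(bottom, initial=0.0) < 0:
        raise ValueError("OCD inputs must be non-negative")
    out = (top + bottom) / 2.0 * thickness * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class LayerStockMap:
    """Per-pixel layer stocks with expected error and AOA status.

    All rasters share the grid's shape; NaN marks nodata (off-mask or
    AOA-masked) — masked pixels are never stored as 0.
    """

    grid: CovariateGrid
    stock: dict[tuple[float, float], np.ndarray]
    error: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    aoa_inside: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    premask: "LayerStockMap | None" = field(default=None, repr=False)

    @property
    def layers(self) -> list[tuple[float, float]]:
        return list(self.stock)

    @property
    def area_ha(self) -> np.ndarray:
        return self.grid.area_ha


def predict_layer_stocks(
    model: FittedModel,
    grid: CovariateGrid,
    layers: tuple[tuple[float, float], ...] = STANDARD_LAYERS,
    chunk_pixels: int = 200_000,
) -> LayerStockMap:
    """Predict OCD at each layer's boundary depths and integrate to stocks.

    Evaluation is chunked over masked pixels so grids larger than memory
    stream through; the result is independent of the chunk size (prediction
    is row-wise).
    """
    rows_idx, cols_idx = grid.masked_indices()
    table = grid.masked_table()
    n = len(table)

    depths = sorted({d for layer in layers for d in layer})
    ocd_at: dict[float, np.ndarray] = {d: np.empty(n) for d in depths}
    for start in range(0, n, max(chunk_pixels, 1)):
        chunk = table.iloc[start : start + chunk_pixels]
        for d in depths:
            ocd_at[d][start : start + len(chunk)] = predict_ocd(model, chunk, d)

    stock: dict[tuple[float, float], np.ndarray] = {}
    for top, bottom in layers:
        values = integrate_stock(ocd_at[top], ocd_at[bottom], bottom - top)
        raster = grid.new_raster()
        raster[rows_idx, cols_idx] = values
        stock[(top, bottom)] = raster
    return LayerStockMap(grid=grid, stock=stock)


def apply_aoa(
    stock_map: LayerStockMap,
    aoa_inside: dict[tuple[float, float], np.ndarray],
) -> LayerStockMap:
    """Mask pixels outside each layer's AOA to nodata.

    Surviving pixel values are taken verbatim from the pre-mask map (no
    recomputation); the unmasked map is retained on ``.premask``. Raises on
    grid-shape mismatch.
    """
    masked_stock: dict[tuple[float, float], np.ndarray] = {}
    masked_error: dict[tuple[float, float], np.ndarray] = {}
    for layer, raster in stock_map.stock.items():
        if layer not in aoa_inside:
            raise ValueError(f"no AOA mask for layer {layer}")
        inside = np.asarray(aoa_inside[layer], dtype=bool)
        if inside.shape != raster.shape:
            raise ValueError(f"AOA mask shape {inside.shape} != grid {raster.shape}")
        out = raster.copy()
        out[~inside] = np.nan
        masked_stock[layer] = out
        if layer in stock_map.error:
            err = stock_map.error[layer].copy()
            err[~inside] = np.nan
            masked_error[layer] = err
    return LayerStockMap(
        grid=stock_map.grid,
        stock=masked_stock,
        error=masked_error,
        aoa_inside={k: np.asarray(v, dtype=bool) for k, v in aoa_inside.items()},
        premask=stock_map,
    )
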