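"""Area-weighted aggregation: 2° cells, regions, global totals, bivariate classes.

Totals are conservative by construction: a pixel belongs to exactly one
cell and at most one region, so cell totals partition the global total and
region totals plus "unassigned" reproduce it exactly. Per-hectare means
are area-weighted over each layer's own inside-AOA pixel set (the two
layers have different AOAs; the deeper one is consistently smaller); the
0–100 cm mean is additionally reported on the intersection set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from marshstock.stocks import LayerStockMap

MG_PER_TG = 1e6  # 1 Tg = 1e6 Mg


def tg_to_pg(tg: float) -> float:
    """Teragrams to petagrams (1 Pg = 1000 Tg)."""
    return tg / 1000.0


def _layer_name(layer: tuple[float, float]) -> str:
    return f"{layer[0]:g}_{layer[1]:g}"


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    if weights.sum() == 0:
        return float("nan")
    return float(np.sum(values * weights) / weights.sum())


def aggregate_cells(
    stock_map: LayerStockMap,
    cell_size: float = 2.0,
    use_premask: bool = False,
) -> pd.DataFrame:
    """Aggregate pixel stocks to ``cell_size``-degree cells.

    Per cell and layer: area-weighted mean stock and error (Mg C ha^-1)
    over inside-AOA pixels (or over all marsh pixels when ``use_premask``,
    for the bivariate prediction/error product), total stock (Tg C) and
    the percentage of marsh pixels inside the AOA. Cells with 0% inside
    are flagged ``displayed = False``.
    """
    grid = stock_map.grid
    source = stock_map.premask if (use_premask and stock_map.premask is not None) else stock_map
    rows_idx, cols_idx = grid.masked_indices()
    lon = grid.lon[cols_idx]
    lat = grid.lat[rows_idx]
    area = grid.area_ha[rows_idx, cols_idx]

    cell_x = np.floor(lon / cell_size).astype(int)
    cell_y = np.floor(lat / cell_size).astype(int)

    frame = pd.DataFrame({"cell_x": cell_x, "cell_y": cell_y, "area_ha": area})
    for layer in source.layers:
        name = _layer_name(layer)
        frame[f"stock_{name}"] = source.stock[layer][rows_idx, cols_idx]
        if layer in source.error:
            frame[f"error_{name}"] = source.error[layer][rows_idx, cols_idx]
        inside = stock_map.aoa_inside.get(layer)
        frame[f"inside_{name}"] = (
            inside[rows_idx, cols_idx] if inside is not None else ~np.isnan(frame[f"stock_{name}"])
        )

    records = []
    for (cx, cy), g in frame.groupby(["cell_x", "cell_y"], sort=True):
        rec = {
            "cell_x": int(cx),
            "cell_y": int(cy),
            "lon_min": cx * cell_size,
            "lon_max": (cx + 1) * cell_size,
            "lat_min": cy * cell_size,
            "lat_max": (cy + 1) * cell_size,
            "marsh_area_ha": float(g["area_ha"].sum()),
        }
        any_inside = False
        for layer in source.layers:
            name = _layer_name(layer)
            inside = g[f"inside_{name}"].to_numpy(dtype=bool)
            valid = inside & g[f"stock_{name}"].notna().to_numpy()
            w = g["area_ha"].to_numpy()[valid]
            s = g[f"stock_{name}"].to_numpy()[valid]
            rec[f"mean_stock_{name}"] = _weighted_mean(s, w)
            rec[f"total_tg_{name}"] = float(np.sum(s * w) / MG_PER_TG) if valid.any() else 0.0
            rec[f"pct_aoa_{name}"] = 100.0 * valid.sum() / len(g)
            if f"error_{name}" in g:
                e = g[f"error_{name}"].to_numpy()
                ev = valid & ~np.isnan(e)
                rec[f"mean_error_{name}"] = _weighted_mean(e[ev], g["area_ha"].to_numpy()[ev])
            any_inside = any_inside or bool(valid.any())
        rec["displayed"] = any_inside
        records.append(rec)
    return pd.DataFrame(records)


def summarize_regions(
    stock_map: LayerStockMap,
    region_labels: np.ndarray,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Per-region and global area-weighted stock summaries.

    ``region_labels`` is a raster of strings (or objects) aligned to the
    grid; masked pixels without a label fall into ``unassigned``. Each
    region row reports marsh area (ha), per-layer area-weighted mean stock
    and expected error over inside-AOA pixels, total stock (Tg C) and %AOA.
    The ``__global__`` row adds the 0–100 cm per-ha mean computed both as
    the sum of per-layer means (each on its own AOA set) and on the common
    inside-AOA pixel set.
    """
    grid = stock_map.grid
    labels = np.asarray(region_labels, dtype=object)
    if labels.shape != grid.shape:
        raise ValueError(f"region label shape {labels.shape} != grid {grid.shape}")
    rows_idx, cols_idx = grid.masked_indices()
    area = grid.area_ha[rows_idx, cols_idx]
    pix_labels = labels[rows_idx, cols_idx]
    pix_labels = np.where(pd.isna(pix_labels), "unassigned", pix_labels)

    layer_values = {}
    for layer in stock_map.layers:
        name = _layer_name(layer)
        s = stock_map.stock[layer][rows_idx, cols_idx]
        inside = ~np.isnan(s)
        e = (
            stock_map.error[layer][rows_idx, cols_idx]
            if layer in stock_map.error
            else np.full_like(s, np.nan)
        )
        layer_values[name] = (s, e, inside)

    def _rows_for(sel: np.ndarray, label: str) -> dict:
        rec = {"region": label, "marsh_area_ha": float(area[sel].sum()), "n_pixels": int(sel.sum())}
        inside_all = np.ones(sel.sum(), dtype=bool)
        mean_sum = 0.0
        for name, (s, e, inside) in layer_values.items():
            v = sel & inside
            w = area[v] if area_weighted else np.ones(v.sum())
            rec[f"mean_stock_{name}"] = _weighted_mean(s[v], w)
            rec[f"total_tg_{name}"] = float(np.nansum(s[v] * area[v]) / MG_PER_TG)
            rec[f"pct_aoa_{name}"] = 100.0 * v.sum() / max(sel.sum(), 1)
            ev = v & ~np.isnan(e)
            we = area[ev] if area_weighted else np.ones(ev.sum())
            rec[f"mean_error_{name}"] = _weighted_mean(e[ev], we)
            inside_all &= inside[sel]
            mean_sum += 0.0 if np.isnan(rec[f"mean_stock_{name}"]) else rec[f"mean_stock_{name}"]
        rec["total_tg"] = sum(rec[f"total_tg_{n}"] for n in layer_values)
        rec["mean_stock_sum_layers"] = mean_sum
        # 1 m mean on the pixels inside *both* layers' AOA
        common = np.zeros_like(sel)
        common[sel] = inside_all
        if common.any():
            w = area[common] if area_weighted else np.ones(common.sum())
            total = np.zeros(common.sum())
            for name, (s, _, _) in layer_values.items():
                total += s[common]
            rec["mean_stock_common_aoa"] = _weighted_mean(total, w)
        else:
            rec["mean_stock_common_aoa"] = float("nan")
        return rec

    records = []
    for region in sorted(set(pix_labels.tolist())):
        records.append(_rows_for(pix_labels == region, str(region)))
    records.append(_rows_for(np.ones_like(area, dtype=bool), "__global__"))
    out = pd.DataFrame(records)
    out["total_pg"] = out["total_tg"].map(tg_to_pg)
    return out


def bivariate_classify(
    cell_table: pd.DataFrame,
    pred_col: str,
    err_col: str,
    pred_threshold: float | None = None,
    err_threshold: float | None = None,
) -> pd.DataFrame:
    """Classify cells into the four prediction x error classes.

    Thresholds default to the medians across cells (echoed in the output
    attributes); classes are ``low``/``high`` per axis, split at <= vs >
    the threshold, so a monotone transform of an axis leaves the median
    split unchanged.
    """
    pred = cell_table[pred_col].to_numpy(dtype=float)
    err = cell_table[err_col].to_numpy(dtype=float)
    if pred_threshold is None:
        pred_threshold = float(np.nanmedian(pred))
    if err_threshold is None:
        err_threshold = float(np.nanmedian(err))
    if np.nanstd(pred) == 0 and np.nanstd(err) == 0:
        warnings.warn("all cells identical; single bivariate class", stacklevel=2)

    out = cell_table.copy()
    out["pred_class"] = np.where(pred > pred_threshold, "high", "low")
    out["err_class"] = np.where(err > err_threshold, "high", "low")
    out["bivariate_class"] = out["pred_class"] + "_pred/" + out["err_class"] + "_err"
    out.attrs["pred_threshold"] = pred_threshold
    out.attrs["err_threshold"] = err_threshold
    return out
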