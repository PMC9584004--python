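"""Geometric and spatial summaries of a detected hearth inventory."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["density", "geometry_report", "build_inventory"]


def density(count: int, reference_area_ha: float) -> dict[str, float]:
    """Hearths per hectare, raw and rounded to one decimal.

    The reference area is typically the forested area rather than the total
    watershed; both can be reported by calling twice.
    """
    if reference_area_ha <= 0:
        raise ValueError("reference area must be positive")
    raw = count / reference_area_ha
    return {"density_per_ha": raw, "density_per_ha_1dp": round(raw, 1)}


def geometry_report(inventory: pd.DataFrame, n_bins: int = 15) -> dict:
    """Descriptive geometry of an inventory of hearths.

    ``inventory`` needs columns ``area_m2`` and ``pa_ratio``; optional
    ``elevation_m`` and ``slope_deg`` enable the Pearson correlations of
    area against elevation and slope (two-sided p from the t approximation).
    Zero-variance variables yield missing correlations.
    """
    out: dict = {"n": int(len(inventory))}
    for col in ("area_m2", "pa_ratio", "elevation_m", "slope_deg",
                "dist_road_m", "dist_building_m"):
        if col in inventory:
            v = inventory[col].to_numpy(dtype=float)
            out[col] = {
                "mean": float(np.mean(v)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
    counts, edges = np.histogram(inventory["area_m2"], bins=n_bins)
    out["area_histogram"] = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    out["correlations"] = {}
    if len(inventory) >= 3:
        for col, key in (("elevation_m", "area_vs_elevation"),
                         ("slope_deg", "area_vs_slope")):
            if col not in inventory:
                continue
            x = inventory["area_m2"].to_numpy(dtype=float)
            y = inventory[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                out["correlations"][key] = {"r": np.nan, "p": np.nan}
                continue
            r, p = stats.pearsonr(x, y)
            out["correlations"][key] = {"r": float(r), "p": float(p)}
    return out


def build_inventory(objects, dem, slope_grid, roads=None, buildings=None) -> pd.DataFrame:
    """Per-hearth inventory: geometry plus terrain sampled at the centroid cell."""
    from .terrain import distance_raster

    rows = []
    road_grid = distance_raster(roads, dem) if roads is not None else None
    bld_grid = distance_raster(buildings, dem) if buildings is not None else None
    for obj in objects:
        x, y = obj.centroid_xy
        r, c = dem.rowcol_of(x, y)
        r = int(np.clip(r, 0, dem.n_rows - 1))
        c = int(np.clip(c, 0, dem.n_cols - 1))
        rec = {
            "label": obj.label,
            "x": x,
            "y": y,
            "area_m2": obj.area_m2,
            "perimeter_m": obj.perimeter_m,
            "pa_ratio": obj.features.get("pa_ratio", obj.perimeter_m / obj.area_m2),
            "elevation_m": float(dem.values[r, c]),
            "slope_deg": float(slope_grid.values[r, c]),
        }
        if road_grid is not None:
            rec["dist_road_m"] = float(road_grid.values[r, c])
        if bld_grid is not None:
            rec["dist_building_m"] = float(bld_grid.values[r, c])
        rows.append(rec)
    return pd.DataFrame(rows)
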