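"""Per-object summary statistics and shape indices.

For every segmented object and every raster layer the pipeline computes the
13 zonal statistics feeding the classifier: minimum, maximum, range, sum,
mean, variance, standard deviation, Gini coefficient and the 0.05 / 0.25 /
0.50 / 0.75 / 0.95 percentiles.  Shape metrics (area, pixel-edge perimeter,
perimeter/area ratio, circularity) are computed from the pixel footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import LabelRaster
from .terrain import CovariateStack

__all__ = [
    "SegmentObject",
    "gini",
    "zonal_summaries",
    "shape_metrics",
    "extract_objects",
]

STAT_NAMES = (
    "min", "max", "range", "sum", "mean", "variance", "sd", "gini",
    "p05", "p25", "p50", "p75", "p95",
)

_PCTS = {"p05": 5, "p25": 25, "p50": 50, "p75": 75, "p95": 95}


def gini(values, mode: str = "population") -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 xbar) of non-negative
    values (``mode="sample"`` uses the n(n-1) denominator instead).

    All-equal values give 0; a zero mean is defined as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("gini requires at least one value")
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    num = np.sum((2 * i - n - 1) * xs)
    if mode == "population":
        return float(num / (n * total))
    if mode == "sample":
        if n < 2:
            return 0.0
        return float(num / ((n - 1) * total))
    raise ValueError("mode must be 'population' or 'sample'")


def _stats_of(x: np.ndarray) -> dict[str, float]:
    out = {
        "min": float(x.min()),
        "max": float(x.max()),
        "sum": float(x.sum()),
        "mean": float(x.mean()),
        "variance": float(x.var()),  # population variance
    }
    out["range"] = out["max"] - out["min"]
    out["sd"] = float(np.sqrt(out["variance"]))
    out["gini"] = gini(x) if x.min() >= 0 else np.nan
    pct = np.percentile(x, list(_PCTS.values()))  # linear interpolation
    for name, v in zip(_PCTS, pct):
        out[name] = float(v)
    return out


def zonal_summaries(labels: LabelRaster, stack) -> pd.DataFrame:
    """13 summary statistics per object x layer, columns ``<layer>_<stat>``.

    ``stack`` is a :class:`CovariateStack` or a mapping name -> grid/array.
    Objects whose values in a layer are all nodata get missing statistics and
    a ``<layer>_n_valid`` of 0 (the count column flags partial coverage).
    Gini is reported as missing for layers with negative values.
    """
    lab = labels.labels
    if isinstance(stack, CovariateStack):
        items = stack.layers.items()
    else:
        items = stack.items()
    ids = np.unique(lab)
    ids = ids[ids > 0]
    out = pd.DataFrame(index=pd.Index(ids, name="label"))
    inside = lab > 0
    lab_in = lab[inside]
    order = np.argsort(lab_in, kind="stable")
    lab_sorted = lab_in[order]
    bounds = np.searchsorted(lab_sorted, np.append(ids, ids[-1] + 1) if ids.size else [])
    for name, layer in items:
        vals = layer.values if hasattr(layer, "values") else np.asarray(layer, float)
        valid = layer.mask() if hasattr(layer, "mask") else ~np.isnan(vals)
        v_in = vals[inside][order]
        ok_in = valid[inside][order]
        cols = {f"{name}_{s}": np.full(ids.size, np.nan) for s in STAT_NAMES}
        nval = np.zeros(ids.size, dtype=int)
        for k in range(ids.size):
            seg = slice(bounds[k], bounds[k + 1])
            x = v_in[seg][ok_in[seg]]
            nval[k] = x.size
            if x.size == 0:
                continue
            st = _stats_of(x)
            for s in STAT_NAMES:
                cols[f"{name}_{s}"][k] = st[s]
        for cname, arr in cols.items():
            out[cname] = arr
        out[f"{name}_n_valid"] = nval
    return out


def _perimeter_edges(mask: np.ndarray) -> int:
    """Number of pixel edges between the region and its complement
    (including the raster border)."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    edges = 0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        shifted = np.roll(padded, (dr, dc), axis=(0, 1))
        edges += int(np.sum(padded & ~shifted))
    return edges


def shape_metrics(pixel_mask: np.ndarray, cell_size_m: float) -> dict[str, float]:
    """Area, perimeter, perimeter/area ratio and circularity of a footprint.

    Perimeter counts exposed pixel edges times the cell size (no Manhattan
    correction).  ``circle_pa_ratio`` is the analytic perimeter/area ratio,
    2 sqrt(pi / area), of a circle with the same surface area.
    """
    mask = np.asarray(pixel_mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty pixel set")
    area = n_px * cell_size_m**2
    perim = _perimeter_edges(mask) * cell_size_m
    return {
        "area_m2": area,
        "perimeter_m": perim,
        "pa_ratio": perim / area,
        "circularity": 4 * np.pi * area / perim**2,
        "circle_pa_ratio": circle_pa_ratio(area),
    }


def circle_pa_ratio(area_m2: float) -> float:
    """Perimeter/area ratio, 2 sqrt(pi/area), of a circle of the given area."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return float(2.0 * np.sqrt(np.pi / area_m2))


@dataclass
class SegmentObject:
    """A labelled region with its footprint, geometry and feature vector."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    centroid_xy: tuple[float, float]
    area_m2: float
    perimeter_m: float
    features: dict[str, float]

    @property
    def n_pixels(self) -> int:
        return self.rows.size


def extract_objects(labels: LabelRaster, stack=None) -> list[SegmentObject]:
    """Materialise SegmentObjects (footprint, centroid, shape, features)."""
    lab = labels.labels
    feat_table = zonal_summaries(labels, stack) if stack is not None else None
    objs = []
    rows_all, cols_all = np.nonzero(lab > 0)
    lab_in = lab[rows_all, cols_all]
    order = np.argsort(lab_in, kind="stable")
    rows_all, cols_all, lab_in = rows_all[order], cols_all[order], lab_in[order]
    ids, starts = np.unique(lab_in, return_index=True)
    starts = np.append(starts, lab_in.size)
    for k, lid in enumerate(ids):
        rows = rows_all[starts[k] : starts[k + 1]]
        cols = cols_all[starts[k] : starts[k + 1]]
        x, y = labels.xy_of(rows, cols)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        mask[rows - r0, cols - c0] = True
        sm = shape_metrics(mask, labels.cell_size_m)
        feats = dict(sm)
        if feat_table is not None and lid in feat_table.index:
            feats.update(feat_table.loc[lid].to_dict())
        objs.append(
            SegmentObject(
                label=int(lid),
                rows=rows,
                cols=cols,
                centroid_xy=(float(x.mean()), float(y.mean())),
                area_m2=sm["area_m2"],
                perimeter_m=sm["perimeter_m"],
                features=feats,
            )
        )
    return objs
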