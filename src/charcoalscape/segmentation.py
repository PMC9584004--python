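"""Seeded region growing segmentation of candidate objects.

Seeds are placed at local minima of the (closed) slope raster below a
flatness quantile, thinned to a minimum spacing.  Regions then grow by a
priority queue: at each step the unassigned 4-neighbour frontier cell whose
feature value is closest to the adjoining region's running mean is attached,
until no frontier cell is within the similarity threshold or the region
reaches its area cap.  Ties are broken by (row, col, region id), making the
result deterministic.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
from scipy import ndimage

from .grids import DemGrid

__all__ = ["LabelRaster", "select_seeds", "region_growing"]


class LabelRaster(DemGrid):
    """Integer region labels co-registered with the source grid; 0 = unassigned.

    Labels are contiguous positive integers; each region is 4-connected.
    """

    @property
    def labels(self) -> np.ndarray:
        return self.values.astype(np.int64)

    @property
    def n_regions(self) -> int:
        return int(self.values.max())


def _as_grid(raster) -> DemGrid:
    if isinstance(raster, DemGrid):
        return raster
    return DemGrid(np.asarray(raster, dtype=float), cell_size_m=1.0)


def select_seeds(
    closed_slope,
    min_distance_m: float = 15.0,
    flatness_quantile: float = 0.03,
) -> list[tuple[int, int]]:
    """Seed cells at local minima of the raster below the flatness quantile.

    Candidates are cells not exceeding any 8-neighbour and not exceeding the
    ``flatness_quantile`` value of the raster; they are greedily thinned in
    order of increasing value (ties by row, col) so that no two seeds are
    closer than ``min_distance_m``.  Returns (row, col) tuples; empty, with a
    warning, when no cell lies below the quantile.
    """
    grid = _as_grid(closed_slope)
    if grid.values.size == 0:
        raise ValueError("raster must be non-empty")
    valid = grid.mask()
    vals = np.where(valid, grid.values, np.inf)
    thr = np.quantile(grid.values[valid], flatness_quantile)
    local_min = vals <= ndimage.minimum_filter(vals, size=3, mode="reflect")
    cand = valid & local_min & (vals <= thr)
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        warnings.warn("no cell below the flatness quantile; no seeds selected")
        return []
    order = np.lexsort((cols, rows, vals[rows, cols]))
    rows, cols = rows[order], cols[order]

    # greedy spacing via a coarse bucket grid at the exclusion radius
    min_px = min_distance_m / grid.cell_size_m
    bucket = max(min_px, 1.0)
    kept_rows: list[int] = []
    kept_cols: list[int] = []
    buckets: dict[tuple[int, int], list[int]] = {}
    for r, c in zip(rows, cols):
        br, bc = int(r // bucket), int(c // bucket)
        ok = True
        for dbr in (-1, 0, 1):
            for dbc in (-1, 0, 1):
                for k in buckets.get((br + dbr, bc + dbc), ()):
                    if (r - kept_rows[k]) ** 2 + (c - kept_cols[k]) ** 2 < min_px**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((br, bc), []).append(len(kept_rows))
            kept_rows.append(int(r))
            kept_cols.append(int(c))
    return list(zip(kept_rows, kept_cols))


def region_growing(
    feature_rasters,
    seeds,
    similarity_threshold: float,
    max_area_m2: float = 340.0,
    cell_size_m: float | None = None,
) -> LabelRaster:
    """Grow one region per seed over the feature raster(s).

    ``feature_rasters`` may be a single grid/array or a list of them (a
    multi-layer feature distance is the Euclidean distance over standardised
    layers).  A frontier cell joins the adjacent region with the smallest
    absolute difference between its feature vector and the region's running
    mean, provided that distance does not exceed ``similarity_threshold`` and
    the region is below ``max_area_m2``.
    """
    if similarity_threshold <= 0:
        raise ValueError("similarity_threshold must be positive")
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")

    if isinstance(feature_rasters, (list, tuple)):
        grids = [_as_grid(r) for r in feature_rasters]
        ref = grids[0]
        feats = np.stack(
            [(g.values - np.mean(g.valid_values())) / (np.std(g.valid_values()) or 1.0)
             for g in grids],
            axis=-1,
        )
        valid = np.logical_and.reduce([g.mask() for g in grids])
    else:
        ref = _as_grid(feature_rasters)
        feats = ref.values[..., None]
        valid = ref.mask()
    if cell_size_m is None:
        cell_size_m = ref.cell_size_m
    max_cells = int(np.floor(max_area_m2 / cell_size_m**2))

    n, m = ref.shape
    labels = np.zeros((n, m), dtype=np.int64)
    n_reg = len(seeds)
    sums = np.zeros((n_reg + 1, feats.shape[-1]))
    counts = np.zeros(n_reg + 1, dtype=np.int64)

    def dist_to(region: int, r: int, c: int) -> float:
        mean = sums[region] / counts[region]
        return float(np.sqrt(np.sum((feats[r, c] - mean) ** 2)))

    heap: list[tuple[float, int, int, int]] = []
    for rid, (r, c) in enumerate(seeds, start=1):
        if not valid[r, c]:
            continue
        labels[r, c] = rid
        sums[rid] += feats[r, c]
        counts[rid] += 1
    for rid, (r, c) in enumerate(seeds, start=1):
        if labels[r, c] != rid:
            continue
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n and 0 <= cc < m and valid[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (dist_to(rid, rr, cc), rr, cc, rid))

    while heap:
        d, r, c, rid = heapq.heappop(heap)
        if labels[r, c] != 0 or counts[rid] >= max_cells:
            continue
        d_now = dist_to(rid, r, c)
        if d_now > d + 1e-12:
            # stale priority: the region mean moved since this entry was pushed
            heapq.heappush(heap, (d_now, r, c, rid))
            continue
        if d_now > similarity_threshold:
            continue
        labels[r, c] = rid
        sums[rid] += feats[r, c]
        counts[rid] += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n and 0 <= cc < m and valid[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (dist_to(rid, rr, cc), rr, cc, rid))

    # relabel to contiguous positive integers in seed order
    used = np.unique(labels)
    used = used[used > 0]
    remap = np.zeros(n_reg + 1, dtype=np.int64)
    remap[used] = np.arange(1, used.size + 1)
    labels = remap[labels]
    return LabelRaster(
        labels.astype(float),
        cell_size_m=cell_size_m,
        origin_xy=ref.origin_xy,
        nodata=-1.0,
    )
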