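"""Species composition: proportions, IDW interpolation, change maps, and
the Brillouin diversity index.

Historical composition comes from charcoal fragment counts per hearth,
current composition from basal area per plot; both are converted to
per-unit species proportions and interpolated to rasters by inverse
distance weighting (IDW), sharing neighbour sets across taxa so that the
interpolated proportion surfaces still sum to one cell-wise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .grids import DemGrid

__all__ = [
    "to_proportions",
    "idw_surface",
    "idw_surfaces",
    "idw_accuracy",
    "change_map",
    "brillouin",
    "brillouin_from_basal_area",
]

META_COLUMNS = ("unit_id", "id", "rch_id", "plot_id", "x", "y", "era")
COINCIDENT_EPS = 1e-9


def _taxon_columns(table: pd.DataFrame, taxa=None) -> list[str]:
    if taxa is not None:
        return list(taxa)
    return [c for c in table.columns if c not in META_COLUMNS]


def to_proportions(table: pd.DataFrame, taxa=None) -> pd.DataFrame:
    """Per-row species proportions from counts or basal areas.

    Non-taxon columns (ids, coordinates, era tag) pass through unchanged.
    Rows with a zero total are dropped with a warning.  A merged
    indistinct category (e.g. Larix/Picea charcoal that cannot be told
    apart anatomically) is just another taxon column and is preserved.
    """
    cols = _taxon_columns(table, taxa)
    vals = table[cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    totals = vals.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total rows")
    out = table.loc[keep].copy()
    out[cols] = vals[keep] / totals[keep, None]
    return out


def _idw_predict(tree, values, query_xy, power, n_neighbours):
    """IDW prediction at query points; ``values`` may be (n,) or (n, k).

    Neighbour sets and weights are shared across value columns, so a set of
    proportion columns predicted together preserves its cell-wise closure.
    Predictions are clamped to the range of the samples actually used.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    V = values[:, None] if single else values
    k = min(n_neighbours, tree.n)
    d, idx = tree.query(query_xy, k=k)
    if d.ndim == 1:  # k == 1
        d = d[:, None]
        idx = idx[:, None]
    with np.errstate(divide="ignore"):
        w = d ** (-float(power))
    coincident = d < COINCIDENT_EPS
    any_coinc = coincident.any(axis=1)
    w[any_coinc] = coincident[any_coinc].astype(float)  # exact interpolator
    neigh = V[idx]  # (nq, k, ncol)
    pred = np.einsum("qk,qkc->qc", w, neigh) / w.sum(axis=1)[:, None]
    pred = np.clip(pred, neigh.min(axis=1), neigh.max(axis=1))
    return pred[:, 0] if single else pred


def idw_surface(
    points_xy,
    values,
    grid: DemGrid,
    power: float = 2.0,
    n_neighbours: int = 50,
) -> DemGrid:
    """Inverse-distance-weighted surface of one variable on ``grid``.

    Weights are d^(-power) over the ``n_neighbours`` nearest samples
    (a variable search radius).  An exact interpolator: a cell coincident
    with a sample returns that sample's value.  Never extrapolates beyond
    the range of the samples used for a cell.
    """
    out = idw_surfaces(points_xy, np.asarray(values, float)[:, None], grid,
                       power=power, n_neighbours=n_neighbours)
    return out[0]


def idw_surfaces(points_xy, values, grid, power=2.0, n_neighbours=50):
    """IDW of several columns at once with shared neighbour sets."""
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("at least one sample point is required")
    if power <= 0:
        raise ValueError("power must be positive")
    tree = cKDTree(pts)
    x, y = grid.cell_centers()
    q = np.column_stack([x.ravel(), y.ravel()])
    pred = _idw_predict(tree, values, q, power, n_neighbours)
    return [grid.like(pred[:, j].reshape(grid.shape)) for j in range(pred.shape[1])]


def idw_accuracy(
    points_xy, values, power: float = 2.0, n_neighbours: int = 50
) -> dict[str, float]:
    """Leave-one-out interpolation accuracy: ME, MAE, RMSE and the R^2 of
    the predicted-vs-measured least-squares fit.

    Each sample is predicted from all remaining samples with the same IDW
    parameters used for mapping.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    vals = np.asarray(values, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("leave-one-out accuracy requires at least 3 points")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        tree = cKDTree(pts[mask])
        preds[i] = _idw_predict(tree, vals[mask], pts[i][None, :], power, n_neighbours)[0]
    err = preds - vals
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(vals) == 0 or np.std(preds) == 0:
        r2 = np.nan if np.std(vals) != np.std(preds) else 1.0
        if mae == 0:
            r2 = 1.0
    else:
        r2 = float(stats.linregress(vals, preds).rvalue ** 2)
    return {"ME": me, "MAE": mae, "RMSE": rmse, "R2": r2}


def change_map(current: DemGrid, historical: DemGrid) -> DemGrid:
    """Cell-wise proportion change, current minus historical, in [-1, 1]."""
    if current.shape != historical.shape:
        raise ValueError("rasters must be co-registered (shape mismatch)")
    diff = current.values - historical.values
    valid = current.mask() & historical.mask()
    out = np.where(valid, diff, current.nodata)
    return current.like(out)


def brillouin(abundances, int_tolerance: float = 1e-9) -> float:
    """Brillouin diversity H = (ln N! - sum ln n_i!) / N of a fully censused
    collection of integer abundances (computed via log-gamma).

    Zero for a single species; maximal, at fixed N, when abundances are as
    even as possible.  Non-integer inputs beyond ``int_tolerance`` raise --
    convert continuous measures first (see
    :func:`brillouin_from_basal_area`).
    """
    x = np.asarray(abundances, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if np.any(np.abs(x - np.round(x)) > int_tolerance):
        raise ValueError("Brillouin requires integer abundances")
    n = np.round(x)
    n = n[n > 0]
    total = n.sum()
    if total < 1:
        raise ValueError("total abundance must be at least 1")
    return float((gammaln(total + 1) - np.sum(gammaln(n + 1))) / total)


def brillouin_from_basal_area(basal_areas, scale: float = 10.0) -> float:
    """Brillouin index of basal areas (m^2/ha) scaled by ``scale`` and
    rounded to integer pseudo-counts.

    The index is defined for counts; this scaling-and-rounding rule is an
    explicit interpretation for continuous abundance and is configurable.
    """
    x = np.round(np.asarray(basal_areas, dtype=float) * scale)
    return brillouin(x)
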