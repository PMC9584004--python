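"""Terrain covariates derived from a DTM.

Implements the raster predictors used throughout the analysis: slope and
aspect (Horn's 3x3 method), Riley's terrain ruggedness index (TRI), the
standard-deviation roughness variant, topographic position index (TPI),
McCune-Keon heat load index (HLI), topographic wetness index (TWI, D8
single-flow-direction), Euclidean distance to features and Gaussian kernel
density of points.

Cells marked nodata are excluded from every neighbourhood statistic and
propagate as nodata in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree

from .grids import DemGrid

__all__ = [
    "CovariateStack",
    "slope",
    "aspect",
    "terrain_indices",
    "tri_riley",
    "roughness_sd",
    "tpi",
    "hli",
    "twi",
    "proximity_layers",
    "distance_raster",
    "kernel_density",
]


@dataclass
class CovariateStack:
    """Named raster layers co-registered with a reference grid."""

    reference: DemGrid
    layers: dict[str, DemGrid] = field(default_factory=dict)

    def add(self, name: str, grid: DemGrid) -> None:
        if not self.reference.same_georef(grid):
            raise ValueError(f"layer {name!r} is not co-registered with the stack")
        self.layers[name] = grid

    def __getitem__(self, name: str) -> DemGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return list(self.layers)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def _padded(dem: DemGrid) -> tuple[np.ndarray, np.ndarray]:
    """Reflect-padded elevation with nodata neighbours replaced by the centre.

    Returns (padded z, valid mask of the original grid).
    """
    z = dem.values.copy()
    valid = dem.mask()
    # fill invalid cells with the nearest valid value so windows never see the
    # sentinel; fully-invalid output cells are masked afterwards
    if not valid.all():
        idx = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True
        )
        z = z[tuple(idx)]
    return np.pad(z, 1, mode="reflect"), valid


def _horn_gradients(dem: DemGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dz/dx, dz/dy, valid) by Horn's 3x3 weighted finite differences.

    x increases with column (east), y increases with decreasing row (north).
    """
    zp, valid = _padded(dem)
    c = dem.cell_size_m
    z = {
        (di, dj): zp[1 + di : zp.shape[0] - 1 + di, 1 + dj : zp.shape[1] - 1 + dj]
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
    }
    dzdx = (
        (z[(-1, 1)] + 2 * z[(0, 1)] + z[(1, 1)])
        - (z[(-1, -1)] + 2 * z[(0, -1)] + z[(1, -1)])
    ) / (8 * c)
    # row index increases southwards, so the northward derivative flips sign
    dzdy = (
        (z[(-1, -1)] + 2 * z[(-1, 0)] + z[(-1, 1)])
        - (z[(1, -1)] + 2 * z[(1, 0)] + z[(1, 1)])
    ) / (8 * c)
    return dzdx, dzdy, valid


def slope(dem: DemGrid) -> DemGrid:
    """Slope in degrees by Horn's method; edges use reflected elevations."""
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("slope requires a raster of at least 3x3 cells")
    dzdx, dzdy, valid = _horn_gradients(dem)
    s = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    s[~valid] = dem.nodata
    return dem.like(s)


def aspect(dem: DemGrid) -> DemGrid:
    """Downslope azimuth in degrees clockwise from north; flat cells -> 0."""
    dzdx, dzdy, valid = _horn_gradients(dem)
    az = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    az[(dzdx == 0) & (dzdy == 0)] = 0.0
    az[~valid] = dem.nodata
    return dem.like(az)


# ---------------------------------------------------------------------------
# roughness / position indices
# ---------------------------------------------------------------------------

def tri_riley(dem: DemGrid) -> DemGrid:
    """Riley terrain ruggedness index: sqrt(sum of squared centre-neighbour
    elevation differences over the 8-neighbourhood)."""
    zp, valid = _padded(dem)
    n, m = dem.shape
    acc = np.zeros((n, m))
    centre = zp[1 : n + 1, 1 : m + 1]
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            acc += (centre - zp[1 + di : n + 1 + di, 1 + dj : m + 1 + dj]) ** 2
    out = np.sqrt(acc)
    out[~valid] = dem.nodata
    return dem.like(out)


def roughness_sd(dem: DemGrid, radius_m: float = 5.0) -> DemGrid:
    """Standard deviation of elevation in a disc neighbourhood (the common
    'roughness' variant distinct from Riley's TRI)."""
    foot = _disc_footprint(radius_m, dem.cell_size_m)
    valid = dem.mask()
    z = np.where(valid, dem.values, 0.0)
    w = valid.astype(float)
    k = foot.astype(float)
    n = signal.fftconvolve(w, k, mode="same")
    s1 = signal.fftconvolve(z, k, mode="same")
    s2 = signal.fftconvolve(z * z, k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / n - (s1 / n) ** 2
    out = np.sqrt(np.clip(var, 0.0, None))
    out[~valid | (n < 1)] = dem.nodata
    return dem.like(out)


def _disc_footprint(radius_m: float, cell: float, exclude_center: bool = False):
    r_px = max(int(np.floor(radius_m / cell)), 1)
    dy, dx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    foot = (dx * dx + dy * dy) * cell**2 <= radius_m**2
    if exclude_center:
        foot[r_px, r_px] = False
    return foot


def tpi(dem: DemGrid, radius_m: float = 10.0) -> DemGrid:
    """Topographic position index: centre elevation minus the mean elevation
    of the surrounding disc annulus (centre cell excluded).

    Positive on ridges and knolls, negative in channels and hollows.
    """
    foot = _disc_footprint(radius_m, dem.cell_size_m, exclude_center=True)
    valid = dem.mask()
    z = np.where(valid, dem.values, 0.0)
    w = valid.astype(float)
    k = foot.astype(float)
    n = signal.fftconvolve(w, k, mode="same")
    s = signal.fftconvolve(z, k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
    out = dem.values - mean
    out[~valid | (n < 1)] = dem.nodata
    return dem.like(out)


# ---------------------------------------------------------------------------
# heat load index
# ---------------------------------------------------------------------------

_HLI_COEF = {
    # McCune & Keon (2002) equations; 1 and 2 model ln(radiation), 3 is direct.
    1: dict(exp=True, c0=-1.467, c1=1.582, c_fold_lat=-1.500, c2=-0.262, c_sin=0.607),
    2: dict(exp=True, c0=-1.236, c1=1.350, c_fold_lat=-1.376, c2=-0.331, c_sin=0.375),
    3: dict(exp=False, c0=0.339, c1=0.808, c2=-0.196, c_fold=-0.482),
}


def hli(dem: DemGrid, latitude_deg: float | None = None, equation: int = 3) -> DemGrid:
    """McCune-Keon heat load index from slope, folded aspect and latitude.

    Aspect is folded about 225 degrees, ``folded = |180 - |aspect - 225||``,
    making south-west the hottest exposure.  ``equation`` selects among the
    three published fits; 3 (the default) is the direct (non-log) form.
    """
    if latitude_deg is None:
        raise ValueError("hli requires the site latitude in degrees")
    if equation not in _HLI_COEF:
        raise ValueError("equation must be 1, 2 or 3")
    coef = _HLI_COEF[equation]
    slope_grid = slope(dem)
    s = np.radians(np.where(slope_grid.mask(), slope_grid.values, 0.0))
    asp = aspect(dem).values
    folded = np.radians(np.abs(180.0 - np.abs(asp - 225.0)))
    lat = np.radians(latitude_deg)
    if coef["exp"]:
        val = (
            coef["c0"]
            + coef["c1"] * np.cos(lat) * np.cos(s)
            + coef["c_fold_lat"] * np.cos(folded) * np.sin(s) * np.sin(lat)
            + coef["c2"] * np.sin(lat) * np.sin(s)
            + coef["c_sin"] * np.sin(folded) * np.sin(s)
        )
        out = np.exp(val)
    else:
        out = (
            coef["c0"]
            + coef["c1"] * np.cos(lat) * np.cos(s)
            + coef["c2"] * np.sin(lat) * np.sin(s)
            + coef["c_fold"] * np.cos(folded) * np.sin(s)
        )
    valid = dem.mask()
    out[~valid] = dem.nodata
    return dem.like(out)


# ---------------------------------------------------------------------------
# topographic wetness index
# ---------------------------------------------------------------------------

_D8_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)
_D8_DIST = np.hypot(_D8_OFFSETS[:, 0], _D8_OFFSETS[:, 1])


def flow_accumulation_d8(dem: DemGrid) -> np.ndarray:
    """D8 single-flow-direction accumulation, in cells (each cell counts itself).

    Every cell routes its accumulated area to the steepest-descent neighbour;
    pits and cells on the boundary with no lower neighbour route nowhere.
    """
    z = np.where(dem.mask(), dem.values, np.inf)
    n, m = z.shape
    zp = np.pad(z, 1, mode="constant", constant_values=np.inf)
    centre = zp[1 : n + 1, 1 : m + 1]
    best_drop = np.zeros((n, m))
    recv = np.full((n, m), -1, dtype=np.int64)
    flat = np.arange(n * m).reshape(n, m)
    flat_p = np.pad(flat, 1, mode="constant", constant_values=-1)
    for (di, dj), dist in zip(_D8_OFFSETS, _D8_DIST):
        nb = zp[1 + di : n + 1 + di, 1 + dj : m + 1 + dj]
        drop = (centre - nb) / dist
        better = drop > best_drop
        best_drop = np.where(better, drop, best_drop)
        recv_ids = flat_p[1 + di : n + 1 + di, 1 + dj : m + 1 + dj]
        recv = np.where(better, recv_ids, recv)
    acc = np.ones(n * m)
    acc[~dem.mask().ravel()] = 0.0
    order = np.argsort(z, axis=None, kind="stable")[::-1]  # high to low
    recv_flat = recv.ravel()
    for cell in order:
        r = recv_flat[cell]
        if r >= 0:
            acc[r] += acc[cell]
    return acc.reshape(n, m)


def twi(dem: DemGrid, min_tan_beta: float = 0.001) -> DemGrid:
    """Topographic wetness index ln(a / tan(beta)).

    ``a`` is the specific contributing area (D8 accumulation x cell area /
    contour width = accumulated cells x cell size); ``tan(beta)`` is floored
    at ``min_tan_beta`` to keep flat cells finite.
    """
    acc = flow_accumulation_d8(dem)
    a = acc * dem.cell_size_m
    s = slope(dem)
    tanb = np.tan(np.radians(np.where(s.mask(), s.values, 0.0)))
    tanb = np.maximum(tanb, min_tan_beta)
    out = np.log(np.maximum(a, dem.cell_size_m) / tanb)
    valid = dem.mask()
    out[~valid] = dem.nodata
    return dem.like(out)


def terrain_indices(
    dem: DemGrid,
    tpi_radius_m: float = 10.0,
    latitude_deg: float | None = None,
    twi_flow: str = "d8",
    roughness_radius_m: float = 5.0,
) -> CovariateStack:
    """Compute the full topographic covariate stack used by the analysis.

    HLI is only computed when ``latitude_deg`` is given; requesting it
    without a latitude raises.  ``twi_flow`` currently supports ``"d8"``.
    """
    if twi_flow != "d8":
        raise ValueError(f"unsupported TWI flow routing {twi_flow!r}")
    stack = CovariateStack(dem)
    stack.add("slope_deg", slope(dem))
    stack.add("tri", tri_riley(dem))
    stack.add("roughness", roughness_sd(dem, roughness_radius_m))
    stack.add("tpi", tpi(dem, tpi_radius_m))
    stack.add("twi", twi(dem))
    if latitude_deg is not None:
        stack.add("hli", hli(dem, latitude_deg))
    return stack


# ---------------------------------------------------------------------------
# distances and kernel density
# ---------------------------------------------------------------------------

def _feature_points(features, densify_m: float) -> np.ndarray:
    """Coerce features to an (n, 2) array of sample points.

    Accepts an array of points or shapely geometries; lines and polygon
    boundaries are densified to vertices at most ``densify_m`` apart, so
    distances to them are accurate to about half that spacing.
    """
    import shapely

    if features is None:
        raise ValueError("feature set must not be empty")
    if isinstance(features, np.ndarray) or (
        isinstance(features, (list, tuple))
        and features
        and not hasattr(features[0], "geom_type")
    ):
        pts = np.atleast_2d(np.asarray(features, dtype=float))
        if pts.size == 0:
            raise ValueError("feature set must not be empty")
        return pts
    coords = []
    for geom in features:
        if geom.geom_type == "Point":
            coords.append(np.asarray(geom.coords))
        else:
            dense = shapely.segmentize(geom, densify_m)
            coords.append(shapely.get_coordinates(dense))
    if not coords:
        raise ValueError("feature set must not be empty")
    return np.vstack(coords)


def distance_raster(features, grid: DemGrid) -> DemGrid:
    """Per-cell planar Euclidean distance (m) to the nearest feature."""
    pts = _feature_points(features, densify_m=grid.cell_size_m / 2.0)
    tree = cKDTree(pts)
    x, y = grid.cell_centers()
    d, _ = tree.query(np.column_stack([x.ravel(), y.ravel()]), k=1)
    return grid.like(d.reshape(grid.shape))


def kernel_density(points, grid: DemGrid, bandwidth_m: float) -> DemGrid:
    """Gaussian kernel density of points, in points per square metre.

    The raster integrates (sum x cell area) to the point count on a grid
    padded by a few bandwidths around the points.
    """
    if bandwidth_m <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("feature set must not be empty")
    c = grid.cell_size_m
    counts = np.zeros(grid.shape)
    row, col = grid.rowcol_of(pts[:, 0], pts[:, 1])
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    np.add.at(counts, (row[inside], col[inside]), 1.0)
    r_px = max(int(np.ceil(4 * bandwidth_m / c)), 1)
    ax = np.arange(-r_px, r_px + 1) * c
    gx = np.exp(-0.5 * (ax / bandwidth_m) ** 2)
    kern = np.outer(gx, gx)
    kern /= kern.sum()
    dens = signal.fftconvolve(counts, kern, mode="same") / (c * c)
    return grid.like(dens)


def proximity_layers(
    rch_points,
    grid: DemGrid,
    kernel_bandwidth_m: float = 50.0,
    roads=None,
    buildings=None,
) -> CovariateStack:
    """Distance-to-feature and RCH kernel-density covariates."""
    stack = CovariateStack(grid)
    stack.add("dist_rch_m", distance_raster(rch_points, grid))
    stack.add("rch_kernel_density", kernel_density(rch_points, grid, kernel_bandwidth_m))
    if roads is not None:
        stack.add("dist_roads_m", distance_raster(roads, grid))
    if buildings is not None:
        stack.add("dist_buildings_m", distance_raster(buildings, grid))
    return stack
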