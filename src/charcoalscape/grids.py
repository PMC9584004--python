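"""Georeferenced single-band raster grids.

The package works in planar metric coordinates.  Rasters are row-major with
the origin at the *upper-left corner* of the grid; the centre of cell
``(row, col)`` is at ``(x0 + (col + 0.5) * cell, y0 - (row + 0.5) * cell)``,
i.e. y decreases with increasing row index (the usual GIS convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DemGrid"]

DEFAULT_NODATA = -9999.0


@dataclass
class DemGrid:
    """A single-band raster with square cells in planar metres.

    Parameters
    ----------
    values
        2-D array (rows, cols).  Stored as float64.
    cell_size_m
        Cell edge length in metres; must be positive.
    origin_xy
        ``(x, y)`` of the upper-left corner of the grid.
    nodata
        Sentinel value marking missing cells.  Cells equal to the sentinel
        (or NaN) never participate in statistics or filters.
    """

    values: np.ndarray
    cell_size_m: float = 1.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DemGrid values must be a 2-D array")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")
        self.origin_xy = (float(self.origin_xy[0]), float(self.origin_xy[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) in metres."""
        return (self.n_cols * self.cell_size_m, self.n_rows * self.cell_size_m)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        v = self.values
        valid = ~np.isnan(v)
        if self.nodata is not None and not np.isnan(self.nodata):
            valid &= v != self.nodata
        return valid

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(x, y)`` of cell-centre coordinates, each shaped like the grid."""
        c = self.cell_size_m
        x0, y0 = self.origin_xy
        xs = x0 + (np.arange(self.n_cols) + 0.5) * c
        ys = y0 - (np.arange(self.n_rows) + 0.5) * c
        return np.meshgrid(xs, ys)

    def xy_of(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        c = self.cell_size_m
        x0, y0 = self.origin_xy
        return x0 + (cols + 0.5) * c, y0 - (rows + 0.5) * c

    def rowcol_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing planar points (x, y)."""
        c = self.cell_size_m
        x0, y0 = self.origin_xy
        col = np.floor((np.asarray(x) - x0) / c).astype(int)
        row = np.floor((y0 - np.asarray(y)) / c).astype(int)
        return row, col

    def like(self, values: np.ndarray, nodata: float | None = None) -> "DemGrid":
        """A new grid sharing this grid's georeferencing."""
        return replace(
            self,
            values=np.asarray(values, dtype=np.float64),
            nodata=self.nodata if nodata is None else nodata,
        )

    def same_georef(self, other: "DemGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size_m - other.cell_size_m) <= atol
            and abs(self.origin_xy[0] - other.origin_xy[0]) <= atol
            and abs(self.origin_xy[1] - other.origin_xy[1]) <= atol
        )
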