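"""Raster and vector format readers/writers.

Rasters: ESRI ASCII grid (``.asc``, plain text, bit-faithful via ``%.10g``)
and GeoTIFF (via :mod:`tifffile`, writing the ModelPixelScale, ModelTiepoint
and GDAL_NODATA tags so standard GIS software picks up the georeferencing).
Vectors: GeoJSON through :mod:`shapely`.  All coordinates are planar metres;
no CRS handling is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
import shapely.geometry as sgeom
import tifffile

from .grids import DemGrid

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_raster",
    "write_raster",
    "read_geojson",
    "write_geojson",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: DemGrid, path) -> Path:
    path = Path(path)
    nrows, ncols = grid.shape
    x0, y0 = grid.origin_xy
    yll = y0 - nrows * grid.cell_size_m
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {grid.cell_size_m:.10g}\n"
        f"NODATA_value {grid.nodata:.10g}\n"
    )
    vals = np.where(grid.mask(), grid.values, grid.nodata)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    return path


def read_ascii_grid(path) -> DemGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})"
        )
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return DemGrid(values, cell_size_m=cell, origin_xy=origin, nodata=nodata)


# ---------------------------------------------------------------------------
# GeoTIFF (minimal: square pixels, single band, planar coordinates)
# ---------------------------------------------------------------------------

def write_geotiff(grid: DemGrid, path) -> Path:
    path = Path(path)
    c = grid.cell_size_m
    x0, y0 = grid.origin_xy
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{grid.nodata:.10g}"),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags)
    return path


def read_geotiff(path) -> DemGrid:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = {tag.code: tag.value for tag in page.tags.values()}
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE, (1.0, 1.0, 0.0))
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
    nodata = float(tags.get(_TAG_GDAL_NODATA, -9999.0))
    cell = float(scale[0])
    # tiepoint maps raster (i, j, k) -> model (x, y, z); we only support the
    # common case of the tiepoint at the raster origin.
    x0 = float(tiepoint[3]) - float(tiepoint[0]) * cell
    y0 = float(tiepoint[4]) + float(tiepoint[1]) * cell
    return DemGrid(values, cell_size_m=cell, origin_xy=(x0, y0), nodata=nodata)


def write_raster(grid: DemGrid, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return write_geotiff(grid, path)
    return write_ascii_grid(grid, path)


def read_raster(path) -> DemGrid:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_geotiff(path)
    return read_ascii_grid(path)


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(geometries, path, properties=None) -> Path:
    """Write shapely geometries (+ optional per-feature property dicts)."""
    path = Path(path)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {
            "type": "Feature",
            "geometry": sgeom.mapping(geom),
            "properties": _jsonify(props),
        }
        for geom, props in zip(geometries, properties, strict=True)
    ]
    with path.open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_geojson(path):
    """Return (list of shapely geometries, list of property dicts)."""
    with Path(path).open() as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        feats = data["features"]
    elif data.get("type") == "Feature":
        feats = [data]
    else:  # bare geometry
        return [sgeom.shape(data)], [{}]
    geoms = [sgeom.shape(f["geometry"]) for f in feats]
    props = [f.get("properties") or {} for f in feats]
    return geoms, props


def _jsonify(props: dict) -> dict:
    out = {}
    for k, v in props.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out
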