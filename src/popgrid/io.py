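"""Raster, vector and table I/O.

Rasters are written as plain TIFF with the grid definition (WGS84 lon/lat,
top-left origin, cell size) embedded as JSON in the image description tag,
plus an optional ``.grid.json`` sidecar for tools that read only metadata.
Vector features travel as GeoJSON via :mod:`shapely`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import shapely
import tifffile

from .grid import GridRaster, AdminIdRaster, Mastergrid


def write_raster(path: str | Path, raster: GridRaster, sidecar: bool = True) -> None:
    path = Path(path)
    meta: dict[str, Any] = {
        "grid": raster.grid.to_dict(),
        "kind": raster.kind,
        "nodata": raster.nodata,
        "crs": "EPSG:4326",
    }
    if isinstance(raster, AdminIdRaster):
        meta["water_code"] = raster.water_code
    tifffile.imwrite(path, raster.values, description=json.dumps(meta))
    if sidecar:
        path.with_suffix(path.suffix + ".grid.json").write_text(
            json.dumps(meta, indent=2))


def read_raster(path: str | Path) -> GridRaster:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    grid = Mastergrid.from_dict(meta["grid"])
    if "water_code" in meta:
        return AdminIdRaster(grid=grid, values=values, nodata=meta["nodata"],
                             water_code=meta["water_code"])
    return GridRaster(grid=grid, values=values, kind=meta["kind"],
                      nodata=meta["nodata"])


# -- GeoJSON ---------------------------------------------------------------

def write_geojson(path: str | Path, features: list[tuple[shapely.Geometry, dict]]) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "geometry": json.loads(shapely.to_geojson(geom)),
             "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[shapely.Geometry, dict]]:
    fc = json.loads(Path(path).read_text())
    feats = fc["features"] if fc.get("type") == "FeatureCollection" else [fc]
    return [
        (shapely.from_geojson(json.dumps(f["geometry"])), f.get("properties") or {})
        for f in feats
    ]


def write_grid_config(path: str | Path, grid: Mastergrid) -> None:
    Path(path).write_text(json.dumps(grid.to_dict(), indent=2))


def read_grid_config(path: str | Path) -> Mastergrid:
    return Mastergrid.from_dict(json.loads(Path(path).read_text()))
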