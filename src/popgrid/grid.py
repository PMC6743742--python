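"""Mastergrid definition and raster harmonisation.

All layers in a popgrid workflow share a single geographic grid (the
*mastergrid*): a north-up, regularly spaced longitude/latitude lattice in
WGS84 decimal degrees, snapped to the global anchor (-180, 90) so that any
two grids of the same cell size align cell-for-cell.  Cells are half-open:
cell (r, c) covers ``[lon0 + c*s, lon0 + (c+1)*s) x (lat0 - (r+1)*s,
lat0 - r*s]`` and is sampled at its centre.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import shapely

logger = logging.getLogger(__name__)

ANCHOR_LON = -180.0
ANCHOR_LAT = 90.0

#: default no-data sentinel for continuous rasters
DEFAULT_NODATA = -99999.0

KINDS = ("continuous", "categorical", "binary")


@dataclass(frozen=True)
class Mastergrid:
    """Geographic grid definition shared by all layers.

    Parameters
    ----------
    cell_size : float
        Cell side in decimal degrees (> 0).
    origin_lon, origin_lat : float
        Top-left corner of the grid, an integer number of cells from the
        global anchor (-180, 90).
    n_rows, n_cols : int
        Grid shape.
    nodata : float
        Default no-data sentinel for rasters on this grid.
    """

    cell_size: float
    origin_lon: float
    origin_lat: float
    n_rows: int
    n_cols: int
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        w, s, e, n = self.bounds
        if not (-180.0 <= w < e <= 180.0 + 1e-9 and -90.0 - 1e-9 <= s < n <= 90.0):
            raise ValueError(f"grid extent {self.bounds} outside the globe")
        if not self.is_snapped():
            raise ValueError(
                "grid origin is not an integer number of cells from the "
                f"(-180, 90) anchor: {(self.origin_lon, self.origin_lat)}"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        s = Fraction(self.cell_size)
        east = float(Fraction(self.origin_lon) + self.n_cols * s)
        south = float(Fraction(self.origin_lat) - self.n_rows * s)
        return (self.origin_lon, south, east, self.origin_lat)

    def is_snapped(self) -> bool:
        """Rational-arithmetic check that the origin lies on the anchor
        lattice.  Exact for cell sizes representable in binary (0.25, 0.5);
        for the rest (0.01, 3 arc-seconds) a 1e-9-cell tolerance absorbs the
        float rounding of the origin itself."""
        s = Fraction(self.cell_size)
        tol = Fraction(1, 10 ** 9)
        for q in ((Fraction(self.origin_lon) - Fraction(ANCHOR_LON)) / s,
                  (Fraction(ANCHOR_LAT) - Fraction(self.origin_lat)) / s):
            k = round(q)
            if abs(q - k) > tol:
                return False
        return True

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell centre."""
        return np.meshgrid(self.lon_centers(), self.lat_centers())

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the half-open cell containing each point.

        Points outside the grid get indices outside ``[0, n_rows) x
        [0, n_cols)``; callers mask with :meth:`in_bounds`.
        """
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row, col) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cell_size": self.cell_size,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "nodata": self.nodata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mastergrid":
        return cls(**{k: d[k] for k in ("cell_size", "origin_lon", "origin_lat",
                                        "n_rows", "n_cols", "nodata")})


@dataclass
class GridRaster:
    """A value matrix aligned to a :class:`Mastergrid`.

    ``kind`` declares how the values behave under resampling and zonal
    statistics: ``continuous`` layers may be interpolated and averaged,
    ``categorical``/``binary`` layers only point-sampled.
    """

    grid: Mastergrid
    values: np.ndarray
    kind: str = "continuous"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.nodata is None:
            self.nodata = self.grid.nodata
        if self.kind == "binary":
            ok = np.isin(self.values, [0, 1]) | (self.values == self.nodata)
            if not ok.all():
                raise ValueError("binary raster contains values outside {0, 1, nodata}")

    @property
    def data_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    nodata=None) -> "GridRaster":
        return GridRaster(self.grid, values, kind or self.kind,
                          self.nodata if nodata is None else nodata)


@dataclass
class AdminIdRaster(GridRaster):
    """Integer unit-ID raster; nodata codes ocean, ``water_code`` inland water."""

    water_code: int = 0

    def __post_init__(self) -> None:
        self.kind = "categorical"
        super().__post_init__()
        if self.water_code != 0 and (self.water_code == self.nodata):
            raise ValueError("water_code must differ from nodata")

    def unit_ids(self) -> np.ndarray:
        v = self.values
        keep = (v != self.nodata) & (v != self.water_code)
        return np.unique(v[keep])

    def unit_mask(self, unit_id: int) -> np.ndarray:
        return self.values == unit_id


def require_same_grid(*rasters: GridRaster) -> Mastergrid:
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise ValueError("rasters are not co-registered (grid definitions differ)")
    return rasters[0].grid


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def define_mastergrid(bounds: Sequence[float], cell_size: float,
                      nodata: float = DEFAULT_NODATA) -> Mastergrid:
    """Smallest anchor-snapped grid fully covering ``bounds``.

    ``bounds`` is (west, south, east, north) in decimal degrees.  The grid
    origin snaps outward to the (-180, 90) anchor lattice, so a request whose
    bounds are already snapped is returned unchanged (snapping is idempotent).
    """
    w, s, e, n = (float(b) for b in bounds)
    if not (w < e and s < n):
        raise ValueError(f"inverted or degenerate bounds {bounds}")
    if not (-180.0 <= w and e <= 180.0 and -90.0 <= s and n <= 90.0):
        raise ValueError(f"bounds {bounds} outside the globe")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")

    cs = Fraction(cell_size)
    tol = Fraction(1, 10 ** 9)
    # outward snap, but treat a bound within 1e-9 cells of a lattice line as
    # already on it so snapping stays idempotent under float rounding
    kw = math.floor(Fraction(w - ANCHOR_LON) / cs + tol)
    kn = math.floor(Fraction(ANCHOR_LAT - n) / cs + tol)
    ke = math.ceil(Fraction(e - ANCHOR_LON) / cs - tol)
    ks = math.ceil(Fraction(ANCHOR_LAT - s) / cs - tol)
    origin_lon = float(Fraction(ANCHOR_LON) + kw * cs)
    origin_lat = float(Fraction(ANCHOR_LAT) - kn * cs)
    return Mastergrid(cell_size=cell_size, origin_lon=origin_lon,
                      origin_lat=origin_lat, n_rows=ks - kn, n_cols=ke - kw,
                      nodata=nodata)


def rasterize_admin_units(polygons: Iterable[tuple[int, shapely.Geometry]],
                          grid: Mastergrid,
                          nodata: int = 0,
                          water_code: int = -1) -> AdminIdRaster:
    """Burn unit polygons onto the grid by cell-centre containment.

    Each cell receives the ID of the polygon containing its centre; where
    overlapping polygons claim the same centre the lowest ID wins (and a
    warning is logged).  Centres inside no polygon are nodata (ocean).
    """
    items = [(int(pid), geom) for pid, geom in
             (polygons.items() if isinstance(polygons, dict) else polygons)]
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("polygon IDs must be unique")
    if any(pid <= 0 for pid in ids):
        raise ValueError("polygon IDs must be positive")

    out = np.full(grid.shape, nodata, dtype=np.int64)
    lon, lat = grid.center_mesh()
    overlap = False
    # descending order: lowest ID overwrites last, hence wins deterministically
    for pid, geom in sorted(items, key=lambda t: -t[0]):
        inside = shapely.intersects_xy(geom, lon, lat)
        if not overlap and np.any(inside & (out != nodata)):
            overlap = True
        out[inside] = pid
    if overlap:
        logger.warning("overlapping admin polygons cover common cell centres; "
                       "lowest ID retained")
    return AdminIdRaster(grid=grid, values=out, nodata=nodata,
                         water_code=water_code)


def integrate_waterbodies(admin: AdminIdRaster, water: GridRaster) -> AdminIdRaster:
    """Merge an inland-water binary layer into the unit-ID raster.

    Census unit boundaries take priority: cells that already carry a unit ID
    keep it even under water.  Cells with no unit and water=1 become the
    water code; everything else is unchanged.
    """
    require_same_grid(admin, water)
    if water.kind != "binary":
        raise ValueError("water layer must be a binary raster")
    out = admin.values.copy()
    underlap = (admin.values == admin.nodata) & (water.values == 1)
    out[underlap] = admin.water_code
    return AdminIdRaster(grid=admin.grid, values=out, nodata=admin.nodata,
                         water_code=admin.water_code)


def align_to_mastergrid(src: GridRaster, target: Mastergrid,
                        method: str = "nearest") -> GridRaster:
    """Resample ``src`` onto ``target``.

    ``nearest`` samples the source cell containing each target centre;
    ``bilinear`` (continuous only) interpolates between the four surrounding
    source centres; ``block_average`` (continuous only) averages the source
    cells whose centres fall inside each target cell, ignoring nodata.
    Target cells with no source coverage are nodata.
    """
    if method not in ("nearest", "bilinear", "block_average"):
        raise ValueError(f"unknown resampling method {method!r}")
    if src.kind in ("categorical", "binary") and method != "nearest":
        raise ValueError(f"{src.kind} rasters may only be resampled with "
                         "'nearest'")
    sw, ss, se, sn = src.grid.bounds
    tw, ts, te, tn = target.bounds
    if se <= tw or te <= sw or sn <= ts or tn <= ss:
        raise ValueError("source and target grids do not overlap")

    sg = src.grid
    if method == "nearest":
        out = np.full(target.shape, src.nodata, dtype=src.values.dtype)
        lon, lat = target.center_mesh()
        row, col = sg.index_of(lon, lat)
        ok = sg.in_bounds(row, col)
        out[ok] = src.values[row[ok], col[ok]]
        result = out
    elif method == "bilinear":
        out = np.full(target.shape, float(src.nodata), dtype=float)
        lon, lat = target.center_mesh()
        # fractional position in source-centre coordinates
        fx = (lon - (sg.origin_lon + 0.5 * sg.cell_size)) / sg.cell_size
        fy = ((sg.origin_lat - 0.5 * sg.cell_size) - lat) / sg.cell_size
        x0 = np.floor(fx).astype(int)
        y0 = np.floor(fy).astype(int)
        wx = fx - x0
        wy = fy - y0
        nd = src.nodata
        interp = np.zeros(target.shape)
        ok = np.ones(target.shape, dtype=bool)
        # neighbours with zero weight (centres exactly on a source centre
        # line) may fall off-grid without invalidating the interpolation
        for dy, dx, wgt in ((0, 0, (1 - wx) * (1 - wy)),
                            (0, 1, wx * (1 - wy)),
                            (1, 0, (1 - wx) * wy),
                            (1, 1, wx * wy)):
            yy, xx = y0 + dy, x0 + dx
            in_rng = ((yy >= 0) & (yy < sg.n_rows)
                      & (xx >= 0) & (xx < sg.n_cols))
            vals = src.values[np.clip(yy, 0, sg.n_rows - 1),
                              np.clip(xx, 0, sg.n_cols - 1)].astype(float)
            needed = wgt > 0
            ok &= ~needed | (in_rng & (vals != nd))
            interp += np.where(needed & in_rng, wgt * vals, 0.0)
        out[ok] = interp[ok]
        result = out
    else:  # block_average
        acc = np.zeros(target.shape, dtype=float)
        cnt = np.zeros(target.shape, dtype=np.int64)
        lon, lat = sg.center_mesh()
        row, col = target.index_of(lon, lat)
        ok = target.in_bounds(row, col) & src.data_mask
        np.add.at(acc, (row[ok], col[ok]), src.values[ok].astype(float))
        np.add.at(cnt, (row[ok], col[ok]), 1)
        out = np.full(target.shape, float(src.nodata), dtype=float)
        covered = cnt > 0
        out[covered] = acc[covered] / cnt[covered]
        result = out

    return GridRaster(grid=target, values=result, kind=src.kind,
                      nodata=src.nodata)


def coastal_fill_nibble(src: GridRaster, land_mask: GridRaster) -> GridRaster:
    """Fill no-data land cells from their nearest data cell ("nibble").

    Land cells (mask=1) lacking data receive the value of the nearest data
    cell by Euclidean distance in cell units; ties break to the smallest row,
    then smallest column.  Ocean cells are forced to nodata; existing data
    cells are never altered.
    """
    require_same_grid(src, land_mask)
    if land_mask.kind != "binary":
        raise ValueError("land_mask must be a binary raster")
    land = land_mask.values == 1
    data = src.data_mask
    gaps = land & ~data
    out = np.where(land, src.values, src.nodata)
    if not gaps.any():
        return src.with_values(out)
    if not data.any():
        raise ValueError("cannot nibble: source raster has no data cells")

    # row-major ordering of data cells makes np.argmin's first-occurrence
    # rule implement the (smallest row, smallest column) tie-break
    dr, dc = np.nonzero(data)
    gr, gc = np.nonzero(gaps)
    chunk = max(1, 10_000_000 // max(len(dr), 1))
    for start in range(0, len(gr), chunk):
        r = gr[start:start + chunk]
        c = gc[start:start + chunk]
        d2 = ((r[:, None] - dr[None, :]) ** 2
              + (c[:, None] - dc[None, :]) ** 2)
        best = np.argmin(d2, axis=1)
        out[r, c] = src.values[dr[best], dc[best]]
    return src.with_values(out)
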