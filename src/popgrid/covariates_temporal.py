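"""Annual time-series covariates.

Night-time-lights annual composites (DMSP two-satellite averaging, VIIRS
observation-weighted monthly compositing with gap fill), the cumulative
protected-area (WDPA-style) annual raster series, and the fused
built-settlement series for 2000/2012/2014.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .grid import GridRaster, Mastergrid, require_same_grid
from .covariates_static import haversine_m

IUCN_GROUPS = ("strict-1", "other")
PA_DOMAINS = ("terrestrial", "marine/coastal")

#: radius used to turn protected-area points into circle proxies, metres
POINT_BUFFER_M = 70.0

WDPA_YEARS = tuple(range(2000, 2018))


@dataclass
class MonthlyStack:
    """One year of monthly radiance composites plus cloud-free observation
    counts (12 months, or 9 for a partial first year)."""

    year: int
    radiance: list[GridRaster]
    observations: list[GridRaster]

    def __post_init__(self) -> None:
        if len(self.radiance) not in (9, 12):
            raise ValueError("expected 9 or 12 monthly rasters")
        if len(self.radiance) != len(self.observations):
            raise ValueError("radiance and observation stacks differ in length")
        require_same_grid(*self.radiance, *self.observations)
        for obs in self.observations:
            if (obs.values[obs.data_mask] < 0).any():
                raise ValueError("observation counts must be non-negative")


@dataclass
class ProtectedArea:
    geometry: shapely.Geometry
    designation_year: int
    iucn_group: str
    domain: str

    def __post_init__(self) -> None:
        if self.iucn_group not in IUCN_GROUPS:
            raise ValueError(f"unknown IUCN group {self.iucn_group!r}")
        if self.domain not in PA_DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.designation_year > 2017:
            raise ValueError("designation year beyond the series end (2017)")


# ---------------------------------------------------------------------------

def dmsp_annual_composite(sat_a: GridRaster,
                          sat_b: GridRaster | None = None) -> GridRaster:
    """Annual DMSP composite: average the two satellites where both report,
    pass single-satellite years through, and replace polar no-coverage
    with zero."""
    if sat_b is not None:
        require_same_grid(sat_a, sat_b)
        a, b = sat_a.values.astype(float), sat_b.values.astype(float)
        am, bm = sat_a.data_mask, sat_b.data_mask
        out = np.zeros(sat_a.grid.shape, dtype=float)
        both = am & bm
        out[both] = (a[both] + b[both]) / 2.0
        only_a = am & ~bm
        out[only_a] = a[only_a]
        only_b = bm & ~am
        out[only_b] = b[only_b]
    else:
        out = np.where(sat_a.data_mask, sat_a.values.astype(float), 0.0)
    return GridRaster(grid=sat_a.grid, values=out, kind="continuous",
                      nodata=sat_a.nodata)


def viirs_annual_composite(stack: MonthlyStack,
                           fill: bool = True,
                           max_fill_iter: int = 10_000) -> GridRaster:
    """Annual VIIRS composite attenuated by months observed.

    Per cell, with m = number of months having at least one cloud-free
    observation: value = (sum of radiance over observed months) / m.  Cells
    with m = 0 are eliminated (nodata) and, when ``fill`` is on, interpolated
    from surrounding values by an iterative 3×3 valid-neighbour mean
    (in-place, row-major sweep) until every cell is filled.
    """
    grid = stack.radiance[0].grid
    nd = stack.radiance[0].nodata
    rad = np.stack([r.values.astype(float) for r in stack.radiance])
    obs = np.stack([o.values for o in stack.observations])
    observed = (obs > 0) & np.stack([o.data_mask for o in stack.observations])
    m = observed.sum(axis=0)
    if (m == 0).all():
        raise ValueError("no cell has any cloud-free observation")
    total = np.where(observed, rad, 0.0).sum(axis=0)
    out = np.full(grid.shape, nd, dtype=float)
    has = m > 0
    out[has] = total[has] / m[has]

    if fill and (~has).any():
        _focal_mean_fill(out, nd, max_fill_iter)
    return GridRaster(grid=grid, values=out, kind="continuous", nodata=nd)


def _focal_mean_fill(values: np.ndarray, nodata: float, max_iter: int) -> None:
    """In-place iterative 3×3 mean fill of nodata cells, row-major sweep."""
    n_rows, n_cols = values.shape
    for _ in range(max_iter):
        todo = np.argwhere(values == nodata)
        if len(todo) == 0:
            return
        changed = False
        for r, c in todo:
            r0, r1 = max(0, r - 1), min(n_rows, r + 2)
            c0, c1 = max(0, c - 1), min(n_cols, c + 2)
            window = values[r0:r1, c0:c1]
            valid = window[window != nodata]
            if valid.size:
                values[r, c] = valid.mean()
                changed = True
        if not changed:
            return
    raise RuntimeError("focal-mean fill did not converge")


# -- protected areas -------------------------------------------------------

def _rasterize_pa(pa: ProtectedArea, grid: Mastergrid) -> np.ndarray:
    """Cells covered by one protected area (points become 70 m circles:
    a cell is covered when its centre lies within the buffer radius)."""
    lon, lat = grid.center_mesh()
    geom = pa.geometry
    if isinstance(geom, shapely.Point):
        d = haversine_m(lon, lat, geom.x, geom.y)
        return d <= POINT_BUFFER_M
    return shapely.intersects_xy(geom, lon, lat)


def wdpa_annual_series(areas: list[ProtectedArea], grid: Mastergrid,
                       years=WDPA_YEARS,
                       ) -> tuple[dict, dict]:
    """Cumulative annual protected-area rasters.

    Returns ``(premosaic, mosaics)``: ``premosaic[(year, group, domain)]`` is
    a binary raster of cells protected by any area of that IUCN group and
    domain designated in or before that year (the first year includes all
    prior designations); ``mosaics[(year, group)]`` unions the terrestrial
    layer onto its marine/coastal counterpart.  For the standard 2000-2017
    span this yields 72 pre-mosaic and 36 final rasters.
    """
    years = sorted(years)
    footprints = [( _rasterize_pa(pa, grid), pa) for pa in areas]

    premosaic: dict[tuple[int, str, str], GridRaster] = {}
    for group in IUCN_GROUPS:
        for domain in PA_DOMAINS:
            cum = np.zeros(grid.shape, dtype=np.uint8)
            sel = [(fp, pa) for fp, pa in footprints
                   if pa.iucn_group == group and pa.domain == domain]
            prev = None
            for year in years:
                for fp, pa in sel:
                    newly = (pa.designation_year <= year if prev is None
                             else prev < pa.designation_year <= year)
                    if newly:
                        cum |= fp.astype(np.uint8)
                prev = year
                premosaic[(year, group, domain)] = GridRaster(
                    grid=grid, values=cum.copy(), kind="binary", nodata=255)

    mosaics: dict[tuple[int, str], GridRaster] = {}
    for year in years:
        for group in IUCN_GROUPS:
            terr = premosaic[(year, group, "terrestrial")].values
            marine = premosaic[(year, group, "marine/coastal")].values
            mosaics[(year, group)] = GridRaster(
                grid=grid, values=(terr | marine).astype(np.uint8),
                kind="binary", nodata=255)
    return premosaic, mosaics


# -- built settlement ------------------------------------------------------

def built_settlement_series(ghsl2000: GridRaster, esa2000_built: GridRaster,
                            guf2012: GridRaster, ghsl2014: GridRaster,
                            ) -> dict[int, GridRaster]:
    """Fused built-settlement binaries for 2000, 2012 and 2014.

    year 2000 = GHSL2000 ∪ (ESA2000-built ∩ GUF2012): ESA built pixels are
    back-filtered by the more reliable GUF radar layer before they may fill
    GHSL gaps.  year 2012 mosaics GUF2012 onto the 2000 layer; year 2014
    mosaics GHSL2014 onto GUF2012.
    """
    grid = require_same_grid(ghsl2000, esa2000_built, guf2012, ghsl2014)
    for r in (ghsl2000, esa2000_built, guf2012, ghsl2014):
        if r.kind != "binary":
            raise ValueError("built-settlement inputs must be binary rasters")
    g00 = ghsl2000.values == 1
    esa = esa2000_built.values == 1
    guf = guf2012.values == 1
    g14 = ghsl2014.values == 1

    y2000 = g00 | (esa & guf)
    y2012 = y2000 | guf
    y2014 = guf | g14

    def as_raster(mask):
        return GridRaster(grid=grid, values=mask.astype(np.uint8),
                          kind="binary", nodata=255)

    return {2000: as_raster(y2000), 2012: as_raster(y2012), 2014: as_raster(y2014)}
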