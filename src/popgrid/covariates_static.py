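"""Time-invariant covariate layers.

Spherical pixel area, Horn slope from elevation, land-cover simplification,
binary/distance derivatives, annual climate summaries, priority-based road
rasterisation and major-highway intersection detection.  All metric
computations use a spherical Earth; the default radius is the authalic
sphere (area-preserving), appropriate for surface-area work on a
geographic lattice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import GridRaster, Mastergrid, require_same_grid

#: authalic sphere radius, metres
AUTHALIC_RADIUS_M = 6_371_007.181

#: priority value reserved for bridge/tunnel "link" ways
LINK_PRIORITY = 30

#: highway classes treated as major routes (tertiary to motorway, plus links)
MAJOR_CLASSES = range(8, 31)

#: classes considered for significant intersections (tertiary to motorway)
INTERSECTION_CLASSES = range(8, 18)


@dataclass(frozen=True)
class EarthModel:
    """Spherical Earth approximation."""

    R: float = AUTHALIC_RADIUS_M

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("Earth radius must be positive")


@dataclass
class PriorityLine:
    """A tagged road/way polyline.

    ``priority`` ranks the road class 1 (footpath) to 17 (motorway); bridges
    and tunnels ("links") carry the reserved value 30 and are flagged so
    that intersection detection can suppress grade-separated crossings.
    """

    geometry: shapely.Geometry
    priority: int
    name: str = ""
    ref: str = ""
    junction: str = ""
    link_flag: bool = False

    def __post_init__(self) -> None:
        if self.link_flag:
            if self.priority != LINK_PRIORITY:
                raise ValueError(f"links must carry priority {LINK_PRIORITY}")
        elif not 1 <= self.priority <= 17:
            raise ValueError("ordinary way priority must be in 1..17")

    @property
    def tag_key(self) -> tuple:
        return (self.name, self.ref, self.junction, self.priority)


# ---------------------------------------------------------------------------

def pixel_area_grid(grid: Mastergrid, earth: EarthModel = EarthModel()) -> GridRaster:
    """Surface area of each cell in m², on the spherical Earth.

    A lon/lat cell spanning Δλ in longitude between latitudes φ_b and φ_t
    has area R²·Δλ·(sin φ_t − sin φ_b); area is constant along rows.
    """
    s = math.radians(grid.cell_size)
    lat_top = np.radians(grid.origin_lat - np.arange(grid.n_rows) * grid.cell_size)
    lat_bot = lat_top - math.radians(grid.cell_size)
    row_area = earth.R ** 2 * s * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(row_area[:, None], grid.n_cols, axis=1)
    return GridRaster(grid=grid, values=values, kind="continuous")


def slope_from_dem(dem: GridRaster, earth: EarthModel = EarthModel()) -> GridRaster:
    """Terrain slope in degrees via the Horn 3×3 finite-difference stencil.

    Horizontal spacing per row is R·cosφ·Δλ (east-west) and R·Δφ
    (north-south).  Border cells and any cell whose 3×3 neighbourhood touches
    nodata are nodata.
    """
    g = dem.grid
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("slope needs at least a 3×3 raster")
    z = dem.values.astype(float)
    nd = dem.nodata
    valid = dem.data_mask

    dlam = math.radians(g.cell_size)
    lat_c = np.radians(g.lat_centers())
    dx = earth.R * np.cos(lat_c) * dlam   # per-row east-west spacing (m)
    dy = earth.R * dlam                    # north-south spacing (m)

    out = np.full(g.shape, nd, dtype=float)
    # interior window views, offsets (dr, dc) relative to centre
    def w(dr, dc):
        return z[1 + dr:g.n_rows - 1 + dr, 1 + dc:g.n_cols - 1 + dc]

    def wv(dr, dc):
        return valid[1 + dr:g.n_rows - 1 + dr, 1 + dc:g.n_cols - 1 + dc]

    all_valid = np.ones((g.n_rows - 2, g.n_cols - 2), dtype=bool)
    for dr, dc in itertools.product((-1, 0, 1), repeat=2):
        all_valid &= wv(dr, dc)

    gx = ((w(-1, 1) + 2 * w(0, 1) + w(1, 1))
          - (w(-1, -1) + 2 * w(0, -1) + w(1, -1))) / (8.0 * dx[1:-1, None])
    gy = ((w(1, -1) + 2 * w(1, 0) + w(1, 1))
          - (w(-1, -1) + 2 * w(-1, 0) + w(-1, 1))) / (8.0 * dy)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    interior = out[1:-1, 1:-1]
    interior[all_valid] = slope[all_valid]
    return GridRaster(grid=g, values=out, kind="continuous", nodata=nd)


# -- land cover ------------------------------------------------------------

#: Synthetic stand-in mapping of ESA-CCI-style land-use codes to nine
#: aggregate classes; replaceable via :func:`mapping_from_csv`.
DEFAULT_LANDCOVER_MAPPING: dict[int, int] = {
    # cropland
    10: 1, 11: 1, 12: 1, 20: 1, 30: 1,
    # mosaic / other vegetation
    40: 2, 100: 2, 110: 2,
    # forest
    50: 3, 60: 3, 61: 3, 62: 3, 70: 3, 71: 3, 72: 3, 80: 3, 81: 3, 82: 3, 90: 3,
    # shrubland / grassland
    120: 4, 121: 4, 122: 4, 130: 4, 140: 4,
    # sparse / bare
    150: 5, 152: 5, 153: 5, 200: 5, 201: 5, 202: 5,
    # wetland
    160: 6, 170: 6, 180: 6,
    # built settlement
    190: 7,
    # water
    210: 8,
    # permanent snow and ice
    220: 9,
}

LANDCOVER_CLASS_LABELS = {
    1: "cropland", 2: "mosaic_vegetation", 3: "forest", 4: "shrub_grassland",
    5: "sparse_bare", 6: "wetland", 7: "built", 8: "water", 9: "snow_ice",
}


def mapping_from_csv(path) -> dict[int, int]:
    """Read a source_code,aggregate_code[,label] reclassification table."""
    df = pd.read_csv(path)
    return dict(zip(df["source_code"].astype(int), df["aggregate_code"].astype(int)))


def mapping_to_csv(mapping: dict[int, int], path,
                   labels: dict[int, str] | None = None) -> None:
    labels = labels or {}
    pd.DataFrame({
        "source_code": list(mapping),
        "aggregate_code": list(mapping.values()),
        "label": [labels.get(v, "") for v in mapping.values()],
    }).to_csv(path, index=False)


def reclassify_landcover(lc: GridRaster,
                         mapping: dict[int, int] | None = None) -> GridRaster:
    """Replace land-use codes by their aggregate class, preserving nodata."""
    if lc.kind != "categorical":
        raise ValueError("land cover must be a categorical raster")
    mapping = DEFAULT_LANDCOVER_MAPPING if mapping is None else mapping
    observed = np.unique(lc.values[lc.data_mask])
    unmapped = sorted(int(v) for v in observed if int(v) not in mapping)
    if unmapped:
        raise ValueError(f"land-cover codes without a mapping entry: {unmapped}")
    out = np.full(lc.grid.shape, lc.nodata, dtype=np.int64)
    for src, agg in mapping.items():
        out[lc.values == src] = agg
    out[~lc.data_mask] = lc.nodata
    return GridRaster(grid=lc.grid, values=out, kind="categorical",
                      nodata=lc.nodata)


def binary_extract(src: GridRaster, classes, mode: str = "binary") -> GridRaster:
    """Membership layer for a set of categorical values.

    ``binary`` mode yields 1/0 on data cells (nodata preserved); ``presence``
    mode yields 1 where the value is in ``classes`` and nodata elsewhere.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    if mode not in ("binary", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    member = np.isin(src.values, classes) & src.data_mask
    out = np.full(src.grid.shape, src.nodata)
    if mode == "binary":
        out[src.data_mask] = 0
    out[member] = 1
    return GridRaster(grid=src.grid, values=out, kind="binary", nodata=src.nodata)


def union_binary(layers: list[GridRaster]) -> GridRaster:
    """Cell-wise union of binary layers (mosaic of presence).

    Used e.g. to assemble the contiguous waterway layer: waterbodies
    mosaicked onto riverbanks, in turn onto waterways — for binary presence
    the mosaic order collapses to a union.
    """
    grid = require_same_grid(*layers)
    out = np.zeros(grid.shape)
    any_data = np.zeros(grid.shape, dtype=bool)
    for layer in layers:
        if layer.kind != "binary":
            raise ValueError("union_binary expects binary layers")
        out[layer.values == 1] = 1
        any_data |= layer.data_mask
    out[~any_data] = layers[0].nodata
    return GridRaster(grid=grid, values=out, kind="binary", nodata=layers[0].nodata)


# -- distance --------------------------------------------------------------

def _unit_vectors(lon_deg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    lon = np.radians(lon_deg)
    lat = np.radians(lat_deg)
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def haversine_m(lon1, lat1, lon2, lat2, R: float = AUTHALIC_RADIUS_M):
    """Great-circle distance in metres between points in degrees."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((p2 - p1) / 2) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2)
    return 2 * R * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def distance_to_feature(feature: GridRaster,
                        earth: EarthModel = EarthModel()) -> GridRaster:
    """Great-circle distance (m) from each cell centre to the nearest
    feature-cell centre; feature cells are 0.

    Nearest neighbours are found in 3-D chord space (chord length is a
    monotone function of great-circle distance, so the nearest chord
    neighbour is the nearest great-circle neighbour), then converted.
    """
    from scipy.spatial import cKDTree

    if feature.kind != "binary":
        raise ValueError("feature layer must be binary")
    mask = feature.values == 1
    if not mask.any():
        raise ValueError("feature raster has no feature cells")
    g = feature.grid
    lon, lat = g.center_mesh()
    feat_xyz = _unit_vectors(lon[mask], lat[mask])
    all_xyz = _unit_vectors(lon.ravel(), lat.ravel())
    chord, _ = cKDTree(feat_xyz).query(all_xyz)
    gc = 2 * earth.R * np.arcsin(np.clip(chord / 2, 0, 1))
    values = gc.reshape(g.shape)
    values[mask] = 0.0
    return GridRaster(grid=g, values=values, kind="continuous", nodata=g.nodata)


def climate_annual(monthly: list[GridRaster], stat: str = "mean") -> GridRaster:
    """Annual climate summary from 12 monthly layers.

    ``mean`` for temperature, ``sum`` for precipitation; a cell nodata in any
    month is nodata in the output.
    """
    if len(monthly) != 12:
        raise ValueError(f"expected 12 monthly rasters, got {len(monthly)}")
    if stat not in ("mean", "sum"):
        raise ValueError(f"unknown stat {stat!r}")
    grid = require_same_grid(*monthly)
    stack = np.stack([m.values.astype(float) for m in monthly])
    valid = np.stack([m.data_mask for m in monthly]).all(axis=0)
    agg = stack.sum(axis=0)
    if stat == "mean":
        agg = agg / 12.0
    out = np.where(valid, agg, monthly[0].nodata)
    return GridRaster(grid=grid, values=out, kind="continuous",
                      nodata=monthly[0].nodata)


# -- roads -----------------------------------------------------------------

def _cell_boxes(grid: Mastergrid, rows: np.ndarray, cols: np.ndarray):
    s = grid.cell_size
    x0 = grid.origin_lon + cols * s
    y1 = grid.origin_lat - rows * s
    return shapely.box(x0, y1 - s, x0 + s, y1)


def priority_rasterize(lines: list[PriorityLine], grid: Mastergrid,
                       retain=MAJOR_CLASSES) -> GridRaster:
    """Maximum retained road-class priority apparent per cell; background 0.

    A line is apparent in a cell when it intersects the cell's closed square.
    Classes outside ``retain`` are dropped (their cells stay 0).
    """
    retain = set(retain)
    out = np.zeros(grid.shape, dtype=np.int64)
    s = grid.cell_size
    for line in lines:
        if line.priority not in retain or line.geometry.length == 0:
            continue
        minx, miny, maxx, maxy = line.geometry.bounds
        c0 = max(0, math.floor((minx - grid.origin_lon) / s))
        c1 = min(grid.n_cols - 1, math.floor((maxx - grid.origin_lon) / s))
        r0 = max(0, math.floor((grid.origin_lat - maxy) / s))
        r1 = min(grid.n_rows - 1, math.floor((grid.origin_lat - miny) / s))
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
        boxes = _cell_boxes(grid, rr.ravel(), cc.ravel())
        hit = shapely.intersects(line.geometry, boxes).reshape(rr.shape)
        sub = out[r0:r1 + 1, c0:c1 + 1]
        np.maximum(sub, np.where(hit, line.priority, 0), out=sub)
    return GridRaster(grid=grid, values=out, kind="categorical", nodata=-1)


def restore_offshore_links(highways: GridRaster, links: GridRaster,
                           land: GridRaster) -> GridRaster:
    """Write offshore bridge/tunnel cells (value 30) back into the highway
    raster so coastal roads stay contiguous; on-land link cells are dropped."""
    require_same_grid(highways, links, land)
    out = highways.values.copy()
    offshore_link = (links.values == LINK_PRIORITY) & (land.values == 0)
    out[offshore_link] = LINK_PRIORITY
    return highways.with_values(out)


def detect_intersections(lines: list[PriorityLine],
                         classes=INTERSECTION_CLASSES) -> list[shapely.Point]:
    """Significant highway intersections among major road classes.

    A point is emitted wherever two ways (both with priority in ``classes``)
    touch or cross and differ in at least one of name, ref, junction or
    priority.  Crossings involving a bridge/tunnel way are suppressed: those
    are grade-separated, not real intersections.  Output is deduplicated and
    sorted, hence independent of input order.
    """
    classes = set(classes)
    major = [ln for ln in lines if ln.priority in classes]
    points: set[tuple[float, float]] = set()
    for a, b in itertools.combinations(major, 2):
        if a.link_flag or b.link_flag:
            continue  # unreachable for 8..17 but kept for custom class sets
        if a.tag_key == b.tag_key:
            continue
        if not shapely.intersects(a.geometry, b.geometry):
            continue
        inter = shapely.intersection(a.geometry, b.geometry)
        for geom in getattr(inter, "geoms", [inter]):
            if geom.is_empty:
                continue
            if isinstance(geom, shapely.Point):
                points.add((round(geom.x, 9), round(geom.y, 9)))
            else:  # collinear overlap: emit its endpoints
                for x, y in np.asarray(geom.coords)[[0, -1]]:
                    points.add((round(float(x), 9), round(float(y), 9)))
    # bridge/tunnel suppression: drop points lying on any link way
    link_geoms = [ln.geometry for ln in lines if ln.link_flag]
    result = []
    for x, y in sorted(points):
        pt = shapely.Point(x, y)
        if any(g.distance(pt) < 1e-9 for g in link_geoms):
            continue
        result.append(pt)
    return result
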