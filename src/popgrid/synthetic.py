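"""Seeded synthetic worlds for end-to-end testing.

Generates toy study regions — admin units, covariate layers, a true
population surface with known generative parameters, two-date censuses,
a prevalence field and event points — so every pipeline stage can be
exercised and scored against ground truth without any real data downloads.

The truth surface is the *expected* population per cell,
``lambda = exp(beta0 + sum(beta_i * z_i) + eps)`` with z-scored covariates,
so zonal census counts equal zonal sums of truth exactly and conservation
checks are bit-exact; a Poisson-sampled variant is available for realism
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter

from .grid import (AdminIdRaster, GridRaster, Mastergrid, coastal_fill_nibble,
                   define_mastergrid, rasterize_admin_units)
from .census import CensusRecord
from .covariates_static import (PriorityLine, distance_to_feature,
                                priority_rasterize)
from .dasymetric import CovariateStack
from .applications import EventSet


def _default_betas() -> dict[str, float]:
    return {"elevation": -0.4, "nightlights": 1.0, "dist_road": -0.4,
            "settlement": 0.8}


@dataclass
class WorldConfig:
    """Generative parameters of a synthetic world.

    Defaults describe a 1°×1° region at 0.01° cells (100×100) with 100
    admin units across 4 countries, log-linear population driven by the
    covariates with moderate unexplained noise (sigma = 0.2 on the log
    scale), and decadal census growth rates between -1%/yr and +3%/yr.
    """

    seed: int
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    cell_size: float = 0.01
    n_countries: int = 4
    units_per_country: int = 25
    beta0: float = 3.0                        # log expected persons per cell
    betas: dict[str, float] = field(default_factory=_default_betas)
    sigma: float = 0.2                        # log-scale noise sd
    growth_range: tuple[float, float] = (-0.01, 0.03)   # 1/year
    year1: float = 2000.5
    year2: float = 2010.5
    prevalence_scale: float = 3.0             # logistic steepness
    prevalence_offset: float = -1.0           # logistic shift (field is ~N(0,1))
    event_rate: float = 60.0                  # Poisson mean events per year
    event_years: tuple[int, ...] = (2000, 2012, 2014)
    n_hotspots: int = 3                       # units attracting events
    hotspot_share: float = 0.8                # fraction of events in hotspots
    subpixel_units: int = 0                   # deliberately unrasterisable units
    poisson_population: bool = False          # sample truth ~ Poisson(lambda)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.units_per_country < 1:
            raise ValueError("units_per_country must be >= 1")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    grid: Mastergrid
    polygons: dict[int, shapely.Geometry]
    admin: AdminIdRaster
    stack: CovariateStack
    truth: GridRaster
    census: list[CensusRecord]
    growth_rates: dict[int, float]
    prevalence: GridRaster
    events: EventSet


def _rng(cfg: WorldConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _sample_in(geom: shapely.Geometry, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bbox."""
    minx, miny, maxx, maxy = geom.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(4 * n, 2))
        inside = shapely.contains_xy(geom, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        pts[got:got + len(take)] = take
        got += len(take)
    return pts


def _voronoi_cells(seeds: np.ndarray, clip: shapely.Geometry) -> list[shapely.Geometry]:
    """Voronoi cell per seed (in seed order), clipped to ``clip``."""
    mp = shapely.MultiPoint(seeds)
    cells = shapely.voronoi_polygons(mp, extend_to=shapely.box(*clip.bounds))
    out: list[shapely.Geometry | None] = [None] * len(seeds)
    for cell in cells.geoms:
        hits = [i for i, (x, y) in enumerate(seeds)
                if cell.intersects(shapely.Point(x, y))]
        for i in hits:
            if out[i] is None:
                out[i] = cell
    return [c.intersection(clip) for c in out]


def simulate_admin_units(cfg: WorldConfig,
                         ) -> tuple[dict[int, shapely.Geometry], AdminIdRaster]:
    """Country/unit partition of the extent (nested Voronoi) plus its raster.

    Unit IDs are ``100*country + index``; parent IDs are the country index.
    When ``cfg.subpixel_units > 0``, that many tiny units (squares smaller
    than a cell, placed to avoid every cell centre) are carved out of large
    units so the sub-pixel merge path can be exercised.
    """
    grid = define_mastergrid(cfg.bounds, cfg.cell_size)
    extent = shapely.box(*cfg.bounds)
    rng = _rng(cfg, 0)

    country_seeds = _sample_in(extent, cfg.n_countries, rng)
    countries = _voronoi_cells(country_seeds, extent)

    polygons: dict[int, shapely.Geometry] = {}
    for ci, country in enumerate(countries, start=1):
        unit_seeds = _sample_in(country, cfg.units_per_country, rng)
        for ui, cell in enumerate(_voronoi_cells(unit_seeds, country), start=1):
            polygons[100 * ci + ui] = cell

    if cfg.subpixel_units > 0:
        hosts = sorted(polygons, key=lambda k: -polygons[k].area)[:cfg.subpixel_units]
        next_id = max(polygons) + 1
        s = grid.cell_size
        for host in hosts:
            pt = polygons[host].representative_point()
            row, col = grid.index_of(pt.x, pt.y)
            # a square of 1/20 cell side tucked in a cell corner: it cannot
            # contain any cell centre, so it never rasterises
            x0 = grid.origin_lon + (int(col) + 0.05) * s
            y0 = grid.origin_lat - (int(row) + 0.15) * s
            tiny = shapely.box(x0, y0, x0 + 0.05 * s, y0 + 0.05 * s)
            tiny = tiny.intersection(polygons[host])
            if tiny.is_empty:
                continue
            polygons[host] = polygons[host].difference(tiny)
            polygons[next_id] = tiny
            next_id += 1

    admin = rasterize_admin_units(polygons.items(), grid)
    return polygons, admin


def simulate_covariates(cfg: WorldConfig, admin: AdminIdRaster) -> CovariateStack:
    """One covariate layer of each kind the pipeline consumes.

    Smooth elevation, derived slope (border nibbled in), clustered binary
    settlement, night lights decaying with distance from settlement plus
    noise, a nine-class categorical land cover, and distance to a random
    toy road network.
    """
    grid = admin.grid
    rng = _rng(cfg, 1)
    shape = grid.shape
    smooth_sigma = max(2.0, min(shape) / 12.0)

    def smooth_field() -> np.ndarray:
        f = gaussian_filter(rng.normal(size=shape), smooth_sigma)
        return (f - f.mean()) / (f.std() + 1e-12)

    elevation = GridRaster(grid, 500.0 + 300.0 * smooth_field(), "continuous")

    from .covariates_static import slope_from_dem
    slope = slope_from_dem(elevation)
    all_land = GridRaster(grid, np.ones(shape, dtype=np.uint8), "binary", nodata=255)
    slope = coastal_fill_nibble(slope, all_land)

    settlement = np.zeros(shape, dtype=np.uint8)
    n_blobs = max(3, (shape[0] * shape[1]) // 1500)
    rr, cc = np.indices(shape)
    for _ in range(n_blobs):
        r0, c0 = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        radius = rng.integers(2, 6)
        settlement[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = 1
    settlement_raster = GridRaster(grid, settlement, "binary", nodata=255)

    from scipy.ndimage import distance_transform_edt
    d_cells = distance_transform_edt(settlement == 0)
    nightlights = 60.0 * np.exp(-d_cells / 5.0) + np.abs(rng.normal(0, 1.0, shape))
    nightlights_raster = GridRaster(grid, nightlights, "continuous")

    lc_field = smooth_field() + 0.3 * rng.normal(size=shape)
    edges = np.quantile(lc_field, np.linspace(0, 1, 9)[1:-1])
    landcover = np.digitize(lc_field, edges) + 1       # classes 1..8
    landcover[settlement == 1] = 9                     # built settlement
    landcover_raster = GridRaster(grid, landcover.astype(np.int64),
                                  "categorical", nodata=-1)

    w, s, e, n = cfg.bounds
    lines = []
    for _ in range(3):
        xs = rng.uniform(w, e, size=3)
        ys = rng.uniform(s, n, size=3)
        lines.append(PriorityLine(shapely.LineString(np.column_stack([xs, ys])),
                                  priority=int(rng.integers(8, 18))))
    roads = priority_rasterize(lines, grid)
    road_binary = GridRaster(grid, (roads.values > 0).astype(np.uint8),
                             "binary", nodata=255)
    if road_binary.values.any():
        dist_road = distance_to_feature(road_binary)
    else:  # pragma: no cover - 3 long lines always hit the toy extent
        dist_road = GridRaster(grid, np.zeros(shape), "continuous")

    return CovariateStack({
        "elevation": elevation,
        "slope": slope,
        "nightlights": nightlights_raster,
        "dist_road": dist_road,
        "settlement": settlement_raster,
        "landcover": landcover_raster,
    })


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / (sd if sd > 0 else 1.0)


def simulate_population(cfg: WorldConfig, admin: AdminIdRaster,
                        stack: CovariateStack,
                        ) -> tuple[GridRaster, list[CensusRecord], dict[int, float]]:
    """True per-cell population and the two-date census table.

    log lambda = beta0 + sum(beta_i * z_i) + eps with eps ~ N(0, sigma²);
    continuous covariates are z-scored, binaries enter as 0/1.  Date-1 unit
    counts are exact zonal sums of the truth; date-2 counts apply a per-unit
    exponential growth rate drawn from ``growth_range``.
    """
    grid = admin.grid
    rng = _rng(cfg, 2)
    log_lam = np.full(grid.shape, cfg.beta0, dtype=float)
    for name, beta in cfg.betas.items():
        layer = stack[name]
        vals = layer.values.astype(float)
        if layer.kind == "binary":
            log_lam += beta * vals
        else:
            log_lam += beta * _zscore(vals)
    if cfg.sigma > 0:
        log_lam += rng.normal(0.0, cfg.sigma, grid.shape)
    lam = np.exp(log_lam)
    if cfg.poisson_population:
        lam = rng.poisson(lam).astype(float)

    unit_cells = (admin.values != admin.nodata) & (admin.values != admin.water_code)
    truth = np.where(unit_cells, lam, 0.0)
    truth_raster = GridRaster(grid, truth, "continuous", nodata=grid.nodata)

    records: list[CensusRecord] = []
    rates: dict[int, float] = {}
    dt = cfg.year2 - cfg.year1
    for uid in admin.unit_ids():
        uid = int(uid)
        p1 = float(truth[admin.values == uid].sum())
        r = float(rng.uniform(*cfg.growth_range))
        rates[uid] = r
        records.append(CensusRecord(unit_id=uid, parent_id=uid // 100,
                                    P1=p1, year1=cfg.year1,
                                    P2=p1 * float(np.exp(r * dt)),
                                    year2=cfg.year2))
    return truth_raster, records, rates


def simulate_prevalence_and_events(cfg: WorldConfig, admin: AdminIdRaster,
                                   polygons: dict[int, shapely.Geometry] | None = None,
                                   ) -> tuple[GridRaster, EventSet]:
    """Logistic-transformed smooth prevalence field plus an inhomogeneous
    point process of events concentrated in hotspot units."""
    grid = admin.grid
    rng = _rng(cfg, 3)
    shape = grid.shape
    f = gaussian_filter(rng.normal(size=shape), max(2.0, min(shape) / 12.0))
    f = (f - f.mean()) / (f.std() + 1e-12)
    prevalence = 1.0 / (1.0 + np.exp(-(cfg.prevalence_scale * f
                                       + cfg.prevalence_offset)))
    prev_raster = GridRaster(grid, prevalence, "continuous", nodata=grid.nodata)

    w, s, e, n = cfg.bounds
    hot_geoms: list[shapely.Geometry] = []
    if polygons and cfg.n_hotspots > 0:
        hot_ids = sorted(polygons)[:cfg.n_hotspots]
        hot_geoms = [polygons[h] for h in hot_ids]

    lons, lats, years = [], [], []
    for year in cfg.event_years:
        n_events = rng.poisson(cfg.event_rate)
        for _ in range(n_events):
            if hot_geoms and rng.uniform() < cfg.hotspot_share:
                geom = hot_geoms[rng.integers(len(hot_geoms))]
                x, y = _sample_in(geom, 1, rng)[0]
            else:
                x, y = rng.uniform(w, e), rng.uniform(s, n)
            lons.append(x)
            lats.append(y)
            years.append(year)
    events = EventSet(np.array(lons, dtype=float), np.array(lats, dtype=float),
                      np.array(years, dtype=int))
    return prev_raster, events


def simulate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Full deterministic world from a config (same seed, same world)."""
    polygons, admin = simulate_admin_units(cfg)
    stack = simulate_covariates(cfg, admin)
    truth, census, rates = simulate_population(cfg, admin, stack)
    prevalence, events = simulate_prevalence_and_events(cfg, admin, polygons)
    return SyntheticWorld(config=cfg, grid=admin.grid, polygons=polygons,
                          admin=admin, stack=stack, truth=truth, census=census,
                          growth_rates=rates, prevalence=prevalence,
                          events=events)
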