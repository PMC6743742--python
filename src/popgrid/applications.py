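"""Demonstration analyses on gridded population.

Two zonal metrics: population at risk under a prevalence threshold (e.g.
malaria parasite rate > 10%) with change metrics between two dates, and
population living in proximity to conflict (inside fixed square zones of
about 9 km side containing two or more recorded events).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AdminIdRaster, GridRaster, Mastergrid, require_same_grid
from .covariates_static import EarthModel

DEFAULT_PREVALENCE_THRESHOLD = 0.10
DEFAULT_ZONE_KM = 9.0
DEFAULT_MIN_EVENTS = 2


@dataclass
class EventSet:
    """Georeferenced events (e.g. conflict incidents) with a year label."""

    lon: np.ndarray
    lat: np.ndarray
    year: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        self.year = np.atleast_1d(np.asarray(self.year, dtype=int))
        if not (len(self.lon) == len(self.lat) == len(self.year)):
            raise ValueError("event coordinate/year arrays differ in length")

    def __len__(self) -> int:
        return len(self.lon)

    def for_year(self, year: int) -> "EventSet":
        sel = self.year == year
        return EventSet(self.lon[sel], self.lat[sel], self.year[sel])


def _zone_sums(values: np.ndarray, zones: AdminIdRaster,
               cell_mask: np.ndarray) -> tuple[pd.Series, pd.Series]:
    ids = zones.values
    unit = (ids != zones.nodata) & (ids != zones.water_code)
    frame = pd.DataFrame({
        "zone": ids[unit],
        "pop": values[unit],
        "sel": np.where(cell_mask, values, 0.0)[unit],
    })
    g = frame.groupby("zone")
    return g["sel"].sum(), g["pop"].sum()


def population_at_risk(pop: GridRaster, prevalence: GridRaster,
                       zones: AdminIdRaster,
                       threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
                       year: int | None = None) -> pd.DataFrame:
    """Per-zone population on cells where prevalence exceeds the threshold.

    Strict inequality (prevalence > threshold) defines "at risk".  Returns a
    table of zone_id, population_at_risk, total_population and
    percent_at_risk.
    """
    require_same_grid(pop, prevalence, zones)
    prev = prevalence.values
    pv = prev[prevalence.data_mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("prevalence must lie in [0, 1]")
    at_risk_cells = prevalence.data_mask & (prev > threshold)
    sel, tot = _zone_sums(np.where(pop.data_mask, pop.values, 0.0),
                          zones, at_risk_cells)
    out = pd.DataFrame({
        "zone_id": sel.index.astype(int),
        "population_at_risk": sel.to_numpy(),
        "total_population": tot.to_numpy(),
    })
    if year is not None:
        out.insert(1, "year", year)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["percent_at_risk"] = 100.0 * out["population_at_risk"] / out["total_population"]
    return out


def risk_change_metrics(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Change in at-risk population between two risk tables.

    Emits log10 of each year's at-risk count, their difference (log10 of the
    ratio), and the percentage-point change.  Zones with a zero at-risk
    count get NaN log fields and a ``log_undefined`` flag rather than a
    fabricated value.
    """
    a = t1.set_index("zone_id")
    b = t2.set_index("zone_id")
    if set(a.index) != set(b.index):
        raise ValueError("risk tables cover different zone sets")
    b = b.loc[a.index]

    def safe_log10(x: np.ndarray) -> np.ndarray:
        out = np.full(x.shape, np.nan)
        pos = x > 0
        out[pos] = np.log10(x[pos])
        return out

    log1 = safe_log10(a["population_at_risk"].to_numpy(float))
    log2 = safe_log10(b["population_at_risk"].to_numpy(float))
    return pd.DataFrame({
        "zone_id": a.index,
        "log10_at_risk_t1": log1,
        "log10_at_risk_t2": log2,
        "log10_change": log2 - log1,
        "percent_point_change": (b["percent_at_risk"] - a["percent_at_risk"]).to_numpy(),
        "log_undefined": np.isnan(log1) | np.isnan(log2),
    })


def conflict_zones(events: EventSet, grid: Mastergrid,
                   zone_km: float = DEFAULT_ZONE_KM,
                   min_events: int = DEFAULT_MIN_EVENTS,
                   earth: EarthModel = EarthModel()) -> GridRaster:
    """Binary raster of fixed square zones containing >= min_events events.

    The extent is partitioned into grid-aligned blocks of about ``zone_km``
    side: block height is the whole number of cell rows closest to zone_km,
    and each block-row's width in cells is set from the metric east-west
    cell size at its central latitude.  All cells of a flagged block are
    marked 1.
    """
    if zone_km <= 0:
        raise ValueError("zone size must be positive")
    deg_per_km_ns = 1000.0 / (earth.R * math.pi / 180.0)
    rows_per_block = max(1, round(zone_km * deg_per_km_ns / grid.cell_size))

    out = np.zeros(grid.shape, dtype=np.uint8)
    if len(events) >= min_events:
        row, col = grid.index_of(events.lon, events.lat)
        ok = grid.in_bounds(row, col)
        row, col = row[ok], col[ok]
        block_row = row // rows_per_block
        # per block-row east-west size from the metric width at its centre
        counts: dict[tuple[int, int], int] = {}
        cols_per_block_cache: dict[int, int] = {}
        for br in np.unique(block_row):
            r_mid = min(grid.n_rows - 1, (br * rows_per_block + rows_per_block // 2))
            lat_mid = grid.origin_lat - (r_mid + 0.5) * grid.cell_size
            ew_deg = zone_km * deg_per_km_ns / max(math.cos(math.radians(lat_mid)), 1e-9)
            cols_per_block_cache[int(br)] = max(1, round(ew_deg / grid.cell_size))
        for r, c, br in zip(row, col, block_row):
            bc = c // cols_per_block_cache[int(br)]
            counts[(int(br), int(bc))] = counts.get((int(br), int(bc)), 0) + 1
        for (br, bc), n in counts.items():
            if n >= min_events:
                cpb = cols_per_block_cache[br]
                r0, r1 = br * rows_per_block, min((br + 1) * rows_per_block, grid.n_rows)
                c0, c1 = bc * cpb, min((bc + 1) * cpb, grid.n_cols)
                out[r0:r1, c0:c1] = 1
    return GridRaster(grid=grid, values=out, kind="binary", nodata=255)


def population_near_conflict(pop: GridRaster, flagged: GridRaster,
                             regions: AdminIdRaster,
                             year: int | None = None) -> pd.DataFrame:
    """Per-region population on flagged (conflict-proximal) cells and its
    share of the regional total; zero-population regions get NaN percent."""
    require_same_grid(pop, flagged, regions)
    sel, tot = _zone_sums(np.where(pop.data_mask, pop.values, 0.0),
                          regions, flagged.values == 1)
    out = pd.DataFrame({
        "zone_id": sel.index.astype(int),
        "population_at_risk": sel.to_numpy(),
        "total_population": tot.to_numpy(),
    })
    if year is not None:
        out.insert(1, "year", year)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(out["total_population"] > 0,
                       100.0 * out["population_at_risk"] / out["total_population"],
                       np.nan)
    out["percent_at_risk"] = pct
    return out
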