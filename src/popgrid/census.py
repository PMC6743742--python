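"""Census time-series interpolation.

Two-date census counts per administrative unit are turned into an annual
2000-2020 series under constant exponential growth:

    r  = ln(P2 / P1) / t          (annualised growth rate, 1/year)
    Px = P2 * exp(r * (x - year2))  (count in target year x)

Units whose two censuses cannot be matched (boundary changes) inherit the
growth rate of their parent (coarser) unit.  Units too small to rasterise
are merged into the neighbouring unit that owns their representative point,
conserving national totals exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import AdminIdRaster

logger = logging.getLogger(__name__)

YEARS = tuple(range(2000, 2021))


@dataclass
class CensusRecord:
    """Two-date census counts for one administrative unit.

    ``P1`` may be NaN when no earlier census could be matched to the unit;
    such records need :func:`fallback_growth_rate` before interpolation.
    """

    unit_id: int
    parent_id: int
    P1: float
    year1: float
    P2: float
    year2: float

    def __post_init__(self) -> None:
        if np.isfinite(self.P1) and self.P1 < 0:
            raise ValueError(f"unit {self.unit_id}: P1 < 0")
        if np.isfinite(self.P2) and self.P2 < 0:
            raise ValueError(f"unit {self.unit_id}: P2 < 0")
        if self.year2 <= self.year1:
            raise ValueError(f"unit {self.unit_id}: year2 must follow year1")

    @property
    def has_valid_pair(self) -> bool:
        return (np.isfinite(self.P1) and np.isfinite(self.P2)
                and self.P1 > 0 and self.P2 > 0)


@dataclass
class GrowthRate:
    unit_id: int
    r: float
    source_level: str = "own"  # "own" | "parent"

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError("growth rate must be finite")


@dataclass
class AnnualCountSeries:
    unit_id: int
    counts: dict[int, float]


def annual_growth_rate(P1: float, P2: float, t: float) -> float:
    """Annualised exponential growth rate between two census counts."""
    if t <= 0:
        raise ValueError("t (years between censuses) must be positive")
    if P1 <= 0 or P2 <= 0:
        logger.warning("non-positive census count (P1=%s, P2=%s); growth rate "
                       "set to 0", P1, P2)
        return 0.0
    return math.log(P2 / P1) / t


def project_population(P2: float, r: float, t: float) -> float:
    """Count ``t`` years after (or, if negative, before) the latest census."""
    if not (math.isfinite(P2) and math.isfinite(r) and math.isfinite(t)):
        raise ValueError("non-finite input to projection")
    return P2 * math.exp(r * t)


def interpolate_census_series(rec: CensusRecord,
                              years=YEARS,
                              rate: GrowthRate | None = None) -> AnnualCountSeries:
    """Annual counts for ``years``, anchored at the latest census.

    ``rate`` overrides the record's own growth rate (parent fallback); by
    default the rate is computed from the record's two censuses.
    """
    if rate is None:
        r = annual_growth_rate(rec.P1, rec.P2, rec.year2 - rec.year1)
    else:
        r = rate.r
    counts = {int(y): project_population(rec.P2, r, y - rec.year2) for y in years}
    return AnnualCountSeries(unit_id=rec.unit_id, counts=counts)


def fallback_growth_rate(children: list[CensusRecord],
                         parents: list[CensusRecord] | CensusRecord) -> list[GrowthRate]:
    """Growth rate per child; unmatched children inherit their parent's rate.

    Children with their own valid two-census pair keep their own rate
    (``source_level='own'``); the rest receive the rate of the parent record
    matching their ``parent_id`` (``source_level='parent'``).
    """
    if isinstance(parents, CensusRecord):
        parents = [parents]
    by_parent = {p.unit_id: p for p in parents}
    orphans = [c.unit_id for c in children
               if not c.has_valid_pair and c.parent_id not in by_parent]
    if orphans:
        raise ValueError(f"children without a usable parent record: {orphans}")

    out: list[GrowthRate] = []
    for c in children:
        if c.has_valid_pair:
            r = annual_growth_rate(c.P1, c.P2, c.year2 - c.year1)
            out.append(GrowthRate(c.unit_id, r, "own"))
        else:
            p = by_parent[c.parent_id]
            if not p.has_valid_pair:
                raise ValueError(f"parent {p.unit_id} lacks a valid census pair")
            r = annual_growth_rate(p.P1, p.P2, p.year2 - p.year1)
            out.append(GrowthRate(c.unit_id, r, "parent"))
    return out


def merge_subpixel_units(table: list[CensusRecord], admin: AdminIdRaster,
                         polygons: dict[int, shapely.Geometry],
                         ) -> tuple[list[CensusRecord], dict[int, int]]:
    """Fold units that rasterised to zero cells into their neighbours.

    A sub-pixel unit's counts (both census dates) are added to the unit
    owning the cell at its polygon's representative point; if that cell is
    nodata/water, the nearest unit-bearing cell is used instead.  Total P1
    and P2 are conserved exactly.  Returns the adjusted table and the
    absorbed-to-absorbing ID mapping.
    """
    present = set(int(u) for u in admin.unit_ids())
    lost = [rec for rec in table if rec.unit_id not in present]
    if not lost:
        return list(table), {}

    grid = admin.grid
    unit_rows, unit_cols = np.nonzero(
        (admin.values != admin.nodata) & (admin.values != admin.water_code))
    if len(unit_rows) == 0:
        raise ValueError("admin raster contains no unit cells to absorb into")

    mapping: dict[int, int] = {}
    merged = {rec.unit_id: CensusRecord(rec.unit_id, rec.parent_id, rec.P1,
                                        rec.year1, rec.P2, rec.year2)
              for rec in table if rec.unit_id in present}
    for rec in lost:
        pt = polygons[rec.unit_id].representative_point()
        row, col = grid.index_of(pt.x, pt.y)
        row, col = int(row), int(col)
        target = None
        if grid.in_bounds(np.array(row), np.array(col)):
            v = int(admin.values[row, col])
            if v != admin.nodata and v != admin.water_code:
                target = v
        if target is None:
            d2 = (unit_rows - row) ** 2 + (unit_cols - col) ** 2
            k = int(np.argmin(d2))
            target = int(admin.values[unit_rows[k], unit_cols[k]])
            logger.info("unit %d representative point on nodata; absorbed into "
                        "nearest unit %d", rec.unit_id, target)
        host = merged[target]
        host.P1 = host.P1 + rec.P1 if np.isfinite(rec.P1) else host.P1
        host.P2 = host.P2 + rec.P2
        mapping[rec.unit_id] = target
    return list(merged.values()), mapping


# -- CSV interfaces --------------------------------------------------------

def records_from_csv(path) -> list[CensusRecord]:
    df = pd.read_csv(path)
    return [CensusRecord(int(r.unit_id), int(r.parent_id), float(r.P1),
                         float(r.year1), float(r.P2), float(r.year2))
            for r in df.itertuples()]


def records_to_csv(records: list[CensusRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def series_to_csv(series: list[AnnualCountSeries], path) -> None:
    rows = [{"unit_id": s.unit_id, "year": y, "count": c}
            for s in series for y, c in sorted(s.counts.items())]
    pd.DataFrame(rows).to_csv(path, index=False)
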