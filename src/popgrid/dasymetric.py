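"""Random-forest dasymetric redistribution.

Census counts are observed per administrative unit; the model learns unit
population *density* (persons/m², log scale) from zonal covariate summaries,
predicts density per pixel, and uses the prediction as a weighting surface
that shares each unit's count among its pixels:

    pop(cell) = count(unit) * w(cell) / sum of w over the unit's cells

Per-unit sums are restored to the input counts exactly after redistribution,
so the output is a disaggregation, never a re-estimate, of the census.
Areal weighting (w = cell land area) is the baseline the model is judged
against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grid import AdminIdRaster, GridRaster, Mastergrid, require_same_grid

#: density floor (persons/m²) keeping zero-count units finite on the log scale
DENSITY_FLOOR = 1e-12


@dataclass
class CovariateStack:
    """Named, co-registered covariate rasters feeding the weighting model."""

    layers: dict[str, GridRaster]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("covariate stack is empty")
        require_same_grid(*self.layers.values())

    @property
    def grid(self) -> Mastergrid:
        return next(iter(self.layers.values())).grid

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def names(self) -> list[str]:
        return list(self.layers)


@dataclass
class DensityModel:
    """Fitted random forest over log population density."""

    forest: RandomForestRegressor
    feature_names: list[str]
    seed: int

    @property
    def importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_,
                         index=self.feature_names)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.forest, path)
        sidecar = {"features": self.feature_names, "seed": self.seed,
                   "importances": self.importances.to_dict(),
                   "format_version": 1}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DensityModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(forest=joblib.load(path), feature_names=meta["features"],
                   seed=meta["seed"])


# ---------------------------------------------------------------------------

def _feature_columns(stack: CovariateStack) -> list[str]:
    """Feature names: continuous layers by name, categorical layers expanded
    to per-class proportion/indicator columns."""
    cols: list[str] = []
    for name, layer in stack.layers.items():
        if layer.kind == "categorical":
            classes = np.unique(layer.values[layer.data_mask])
            cols.extend(f"{name}_prop_{int(k)}" for k in classes)
        else:
            cols.append(name)
    return cols


def zonal_covariate_summary(stack: CovariateStack, admin: AdminIdRaster,
                            areas: GridRaster) -> pd.DataFrame:
    """Per-unit covariate summaries and land area.

    Continuous (and binary) layers are averaged over each unit's data cells;
    categorical layers become per-class proportions summing to 1.  A unit
    with no valid cells for some covariate carries NaN there (flagged
    missingness, not silently zero).  Indexed by unit_id, with a
    ``land_area`` column in m².
    """
    require_same_grid(*stack.layers.values(), admin, areas)
    ids = admin.values.ravel()
    unit_sel = (ids != admin.nodata) & (ids != admin.water_code)
    frame = pd.DataFrame({"unit_id": ids[unit_sel]})

    out = pd.DataFrame(index=np.unique(frame["unit_id"]))
    out.index.name = "unit_id"
    area_vals = areas.values.ravel()[unit_sel]
    out["land_area"] = frame.assign(a=area_vals).groupby("unit_id")["a"].sum()

    for name, layer in stack.layers.items():
        vals = layer.values.ravel()[unit_sel]
        valid = layer.data_mask.ravel()[unit_sel]
        if layer.kind == "categorical":
            classes = np.unique(layer.values[layer.data_mask])
            sub = frame[valid].assign(v=vals[valid])
            counts = sub.groupby("unit_id")["v"].value_counts().unstack(fill_value=0)
            props = counts.div(counts.sum(axis=1), axis=0)
            for k in classes:
                col = props[k] if k in props.columns else 0.0
                out[f"{name}_prop_{int(k)}"] = col
            out.loc[~out.index.isin(sub["unit_id"].unique()),
                    [f"{name}_prop_{int(k)}" for k in classes]] = np.nan
        else:
            sub = frame[valid].assign(v=vals[valid].astype(float))
            out[name] = sub.groupby("unit_id")["v"].mean()
    return out


def fit_density_model(summaries: pd.DataFrame, counts: dict[int, float] | pd.Series,
                      seed: int, n_estimators: int = 500,
                      **forest_kwargs) -> DensityModel:
    """Random-forest regression of log density on unit covariate summaries.

    ``counts`` are persons per unit; density = count / land_area, floored at
    1e-12 persons/m² before the log.  Deterministic under ``seed``.
    """
    counts = pd.Series(counts)
    # canonical unit order so the fit is invariant to input row permutation
    common = summaries.index.intersection(counts.index).sort_values()
    feats = [c for c in summaries.columns if c != "land_area"]
    X = summaries.loc[common, feats].fillna(0.0).to_numpy(float)
    density = counts.loc[common].to_numpy(float) / summaries.loc[common, "land_area"].to_numpy(float)
    if (density > 0).sum() < 10:
        raise ValueError("need at least 10 units with positive density")
    y = np.log(np.maximum(density, DENSITY_FLOOR))
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) density response")
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed,
                                   n_jobs=1, **forest_kwargs)
    forest.fit(X, y)
    return DensityModel(forest=forest, feature_names=feats, seed=seed)


def predict_weight_surface(model: DensityModel, stack: CovariateStack,
                           land: GridRaster) -> GridRaster:
    """Per-pixel weighting surface: exp of the model's log-density prediction.

    Built for every land cell (land=1) with complete covariates; cells with
    any missing covariate, and off-land cells, are nodata.
    """
    grid = require_same_grid(*stack.layers.values(), land)
    cols = _feature_columns(stack)
    missing = [c for c in model.feature_names if c not in cols]
    if missing:
        raise ValueError(f"covariate stack lacks model features: {missing}")

    on_land = land.values == 1
    valid = on_land.copy()
    for layer in stack.layers.values():
        valid &= layer.data_mask
    n = int(valid.sum())
    X = np.empty((n, len(model.feature_names)), dtype=float)
    col_data: dict[str, np.ndarray] = {}
    for name, layer in stack.layers.items():
        v = layer.values[valid]
        if layer.kind == "categorical":
            for k in np.unique(layer.values[layer.data_mask]):
                col_data[f"{name}_prop_{int(k)}"] = (v == k).astype(float)
        else:
            col_data[name] = v.astype(float)
    for j, c in enumerate(model.feature_names):
        X[:, j] = col_data[c]

    out = np.full(grid.shape, float(grid.nodata))
    out[valid] = np.exp(model.forest.predict(X))
    return GridRaster(grid=grid, values=out, kind="continuous",
                      nodata=grid.nodata)


def _exact_partition(count: float, shares: np.ndarray) -> np.ndarray:
    """Split ``count`` proportionally to ``shares`` so the parts sum back to
    it bit-exactly under any summation order.

    Parts are quantised to multiples of the count's ulp: every partial sum
    of such multiples below 2**53 ulps is itself exact, so the quantised
    residual can be folded into the largest part and ``np.sum`` (pairwise),
    ``math.fsum`` and plain accumulation all return exactly ``count``.  The
    quantisation perturbs each part by at most half an ulp of the total —
    far below the 1e-9 relative tolerance of the proportional shares.
    """
    import math

    if count == 0:
        return np.zeros_like(shares)
    if count < 0:
        raise ValueError("counts must be non-negative")
    q = 2.0 ** (math.floor(math.log2(count)) - 52)
    cells = np.round(count * shares / q) * q
    resid = count - cells.sum()
    cells[int(np.argmax(shares))] += resid
    return cells


def redistribute_counts(weights: GridRaster, admin: AdminIdRaster,
                        counts: dict[int, float] | pd.Series,
                        ) -> tuple[GridRaster, pd.DataFrame]:
    """Dasymetric redistribution of unit counts onto the weight surface.

    Cells of each unit share its count in proportion to their weights;
    units whose weights sum to zero (or are entirely nodata) fall back to a
    uniform split over their cells.  A final correction restores each
    unit's pixel sum to its count bit-exactly.  Returns the population
    raster and a per-unit audit table.
    """
    require_same_grid(weights, admin)
    counts = pd.Series(counts)
    present = set(int(u) for u in admin.unit_ids())
    absent = sorted(set(counts.index.astype(int)) - present)
    if absent:
        raise ValueError(
            f"units in counts but not in the admin raster (merge first): {absent}")

    pop = np.zeros(admin.grid.shape, dtype=float)
    w = np.where(weights.data_mask, weights.values, 0.0).astype(float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    audit_rows = []
    for uid, count in counts.items():
        mask = admin.values == uid
        wu = w[mask]
        total = wu.sum()
        if total <= 0:
            shares = np.full(wu.shape, 1.0 / wu.size)
            fallback = True
        else:
            shares = wu / total
            fallback = False
        cell_pop = _exact_partition(float(count), shares)
        pop[mask] = cell_pop
        audit_rows.append({"unit_id": int(uid), "input_count": float(count),
                           "output_sum": float(pop[mask].sum()),
                           "uniform_fallback": fallback})
    audit = pd.DataFrame(audit_rows)
    raster = GridRaster(grid=admin.grid, values=pop, kind="continuous",
                        nodata=admin.grid.nodata)
    return raster, audit


def areal_weight_baseline(admin: AdminIdRaster, areas: GridRaster) -> GridRaster:
    """GPW-style baseline: weight each unit cell by its land area, so the
    redistributed density (persons/m²) is constant within each unit."""
    require_same_grid(admin, areas)
    unit = (admin.values != admin.nodata) & (admin.values != admin.water_code)
    out = np.where(unit, areas.values.astype(float), admin.grid.nodata)
    return GridRaster(grid=admin.grid, values=out, kind="continuous",
                      nodata=admin.grid.nodata)
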