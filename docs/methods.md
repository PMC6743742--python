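# Methods

This note documents the models, conventions and numerical choices behind
`popgrid`, and what the synthetic-world tests do and do not demonstrate
about real data.

## Grid model

All layers live on a *mastergrid*: a north-up lon/lat lattice (WGS84) with
cells of side `s` degrees, snapped so the origin is an integer number of
cells from the global anchor (−180°, 90°). Snapping guarantees any two
grids of equal cell size align cell-for-cell, which is what makes
"harmonisation" meaningful. Conventions the literature usually leaves
implicit, fixed here:

- cells are half-open, `[x, x+s) × (y−s, y]`, sampled at their centre;
- snapping verification uses rational arithmetic (`fractions.Fraction`),
  exact for binary-representable cell sizes and with a 1e-9-cell tolerance
  otherwise, since a float origin such as `−180 + k·0.01` cannot itself be
  exact;
- overlapping admin polygons at a cell centre resolve to the lowest unit
  ID — deterministic and independent of input order — with a logged
  warning;
- the nibble fill assigns each no-data land cell the value of its nearest
  data cell (Euclidean distance in cell units), ties broken to the
  smallest row then column. It is computed directly in floating point; the
  historical integer-tool workaround of scaling values by 10⁶ before
  filling and dividing after is a no-op under this implementation because
  no integer conversion happens.
- rasters are stored as plain TIFF with the grid definition as JSON
  metadata. Georeferencing is carried in that metadata (cell size, origin,
  WGS84), not as GeoTIFF tags; the on-disk pixel layout is identical.

Resampling (`align_to_mastergrid`) offers nearest (only option for
categorical/binary layers), bilinear (four surrounding source centres;
neighbours with zero interpolation weight may fall off-grid without
invalidating the cell), and block average (mean of source cells whose
centres fall in the target cell, ignoring no-data).

## Census interpolation

Counts follow constant exponential growth between two censuses:
`r = ln(P₂/P₁)/t`, `Pₓ = P₂·e^{r(x−year₂)}` for target years 2000–2020.
Choices where the convention is genuinely open:

- `r` is undefined for zero counts; such units get `r = 0` with a warning
  rather than being dropped — a unit with population must stay in the
  series.
- census dates are decimal years; day-level precision is not modelled.
- no floor or cap is applied to negative growth.
- units that rasterise to zero cells are merged into the unit owning the
  cell at their polygon's representative point (guaranteed-interior, unlike
  the centroid of a concave unit); counts at both dates are added, so
  national totals are conserved exactly.

## Covariates

- **Pixel area**: on the authalic sphere (R = 6 371 007.181 m, the
  area-preserving radius, configurable), a cell spanning Δλ between
  latitudes φ_b, φ_t has area `R²·Δλ·(sin φ_t − sin φ_b)`. Summed over any
  full global grid this telescopes to 4πR² to rounding error, which the
  tests assert at 1e-9 relative.
- **Slope**: Horn 3×3 finite differences with metric spacing
  `dx = R·cos φ·Δλ` per row, `dy = R·Δφ`; output `arctan|∇z|` in degrees.
  Border cells and cells whose stencil touches no-data are no-data.
- **Land cover**: source codes map to nine aggregate classes. The shipped
  `DEFAULT_LANDCOVER_MAPPING` is a synthetic stand-in over ESA-CCI-style
  codes (cropland, mosaic, forest, shrub/grassland, sparse/bare, wetland,
  built, water, snow/ice) and is user-replaceable via a
  `source_code,aggregate_code,label` CSV.
- **Distance to feature**: great-circle distance between cell centres,
  computed via a 3-D k-d tree on unit vectors (chord length is monotone in
  great-circle distance, so nearest-chord = nearest-arc) and converted with
  `2R·asin(chord/2)`.
- **Roads**: polylines carry priority classes 1–17 (footpath→motorway);
  bridge/tunnel "links" carry the reserved value 30. Rasterisation takes
  the maximum priority apparent per cell, where a line is apparent if it
  intersects the cell's closed square; classes 8–30 are retained by
  default. Offshore link cells are restored after coastal standardisation
  so coastal roads stay contiguous. Intersections are emitted where two
  ways of class 8–17 touch or cross and differ in name, ref, junction or
  priority; crossings involving a bridge/tunnel are suppressed
  (grade-separated, not real junctions). Whether real junctions also
  require a shared vertex is ambiguous in the field; pure geometric
  touch/cross is used here.
- **Climate**: annual temperature is the mean, precipitation the sum, of
  12 monthly layers; a cell missing any month is missing in the output.
- **Night lights**: DMSP years average two satellites where both report
  and pass single-satellite years through, with polar no-coverage set to
  zero. VIIRS years divide summed monthly radiance by the number of months
  with at least one cloud-free observation; zero-observation cells are
  eliminated and then filled by an iterative 3×3 valid-neighbour mean
  (in-place, row-major sweep — deterministic; no interpolation method is
  canonical for this step, so the simplest convergent one is used).
- **Protected areas**: polygons (points buffered to 70 m circles — a cell
  is covered when its centre lies within the radius) are accumulated
  cumulatively per year 2000–2017, IUCN group (strict category 1 vs other)
  and domain (terrestrial vs marine/coastal): 72 binary rasters, the first
  year including all prior designations. Terrestrial layers are then
  unioned onto their marine/coastal counterparts: 36 final rasters, two per
  year. Cumulative coverage is computed directly rather than via decadal
  batching; the result is identical by construction.
- **Built settlement**: year 2000 = GHSL2000 ∪ (ESA-built ∩ GUF2012) — the
  optical ESA class is back-filtered by the radar GUF layer before filling
  GHSL gaps; 2012 = 2000 ∪ GUF2012; 2014 = GUF2012 ∪ GHSL2014. The stated
  unions imply 2000 ⊆ 2012 but not 2012 ⊆ 2014; no extra monotonicity is
  enforced.

## Dasymetric model

A `RandomForestRegressor` (500 trees, default feature subsampling, no
depth cap, mandatory seed, single-threaded for determinism) regresses
`log(density)` — density = unit count / unit land area in persons/m²,
floored at 1e-12 for zero-count units — on zonal covariate summaries
(means of continuous layers, class proportions of categorical layers).
Units are sorted by ID before fitting so the model is invariant to input
row order. Per-pixel weights are `exp(prediction)` on land cells with
complete covariates; redistribution shares each unit's count
proportionally, falling back to a uniform split when a unit's weights sum
to zero (population must go somewhere).

**Exact conservation.** Proportional shares leave float residuals, and
numpy's pairwise summation means a residual dumped on one cell can
oscillate one ulp around the target forever. Each unit's cell values are
therefore quantised to multiples of the count's ulp: partial sums of such
multiples below 2⁵³ ulps are exact in double precision, so after folding
the (exactly representable) residual into the largest cell, *every*
summation order — `np.sum`, `math.fsum`, serial — returns the census count
bit-exactly. The quantisation moves each cell by at most half an ulp of
the unit total, far below any physical meaning.

Whether one model should serve a country or the whole set of inputs is
left to the caller: the model fits whatever units it is given.

## Synthetic worlds

`WorldConfig` defaults define the reference study conditions: a 1°×1°
extent at 0.01° cells (100×100 — sized so the full suite runs in seconds),
4 countries × 25 Voronoi units, log-linear truth
`λ = exp(β₀ + Σβᵢzᵢ + ε)` with β₀ = 3 (log persons/cell), effects on
z-scored elevation (−0.4), night lights (+1.0), road distance (−0.4) and
binary settlement (+0.8), noise σ = 0.2, growth rates uniform in
[−1%, +3%]/yr between censuses at 2000.5 and 2010.5, a logistic-smoothed
prevalence field, and ~60 events/yr concentrated 80:20 in three hotspot
units. The truth surface is the *expected* count per cell, so census
counts equal zonal truth sums exactly and conservation checks are
bit-exact; `poisson_population=True` samples counts instead for realism
tests. All randomness derives from the single config seed via independent
`SeedSequence` streams per stage, so worlds are byte-identical under a
fixed config.

What passing tests show — and don't. The generator produces smooth Gaussian
fields, disk-shaped settlements and Voronoi units; real covariates have
anisotropy, long-range structure and measurement error, and real census
units have boundary/count inconsistencies the generator does not emulate.
The recovery results (RF beating areal weighting, held-out R² > 0.9 under
noiseless log-linear truth) therefore validate the machinery — zonal
aggregation, model plumbing, conservation — not real-world predictive
accuracy.

## Applications

Population at risk uses a strict prevalence threshold (`> 0.10` by
default) and per-zone masked sums; change metrics emit log₁₀ counts for
both dates and their difference (equivalently log₁₀ of the ratio — both
readings recoverable), with zero counts flagged undefined rather than
fabricated. Conflict zones partition the extent into fixed, grid-aligned
blocks of ~9 km side — block height is the whole number of cell rows
nearest 9 km, each block-row's width set from the metric east-west cell
size at its central latitude — and a block is flagged when it contains ≥2
events. A fixed partition (rather than a moving window) is deterministic
and matches the "zone" framing; the alternative reading would flag
somewhat more area.

## Limitations

- Single-array processing only: grids are assumed to fit in memory (fine
  to a few thousand cells on a side); no tiling or out-of-core paths.
- Geographic coordinates only; no projected CRS support.
- The nibble fill and brute-force rasterisation oracles are O(gaps × data
  cells) / O(cells) and are meant for desk-scale grids.
- No uncertainty quantification on the weighting surface; the RF gives a
  point prediction.
- Age/sex structure, UN-total calibration and per-region covariate
  selection are out of scope.
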