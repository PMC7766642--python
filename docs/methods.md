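# Methods

## Scope and model

`wetscape` quantifies the multi-date dynamics of a focal land-cover class
(canonically alpine wetland) on categorical rasters with square cells. All
computation is purely grid-based: georeferencing beyond the cell size is
carried as opaque metadata. Areas are in hm² (1 hm² = 10⁴ m²) everywhere;
conversions happen only at I/O boundaries.

A *patch* is a maximal set of same-class cells connected under a chosen
adjacency. The default is 8-connectivity (diagonal neighbors join a
patch), the Fragstats convention for categorical land-cover maps;
4-connectivity is available everywhere via a flag. Nodata cells are
excluded from the landscape area A, from patch delineation, and from
transition matrices.

### Indices

For class *i* with patches *j = 1..n* of area *a_ij*:

- **WA** = Σ_j a_ij (hm²); **WP** = 100·WA/A.
- **PN** = n; **PD** = PN/(A/100), i.e. patches per 100 hm² (= per km²).
  Published wetland PD series (≈7000 patches over ≈4.25·10⁶ hm² printed as
  0.167) are consistent only with per-km² scaling, so that unit is used
  and tagged in outputs.
- **LCI** for an interval = ½·|WP(t+1) − WP(t)|.
- **LSI** = 0.25·E/√A with A in m² and E the total boundary length (m).
  E counts each internal cell edge separating two different classes
  *once*, plus every edge against nodata or the grid border. This is the
  Fragstats landscape-level edge total; the alternative
  sum-of-patch-perimeters reading would double-count internal edges. Both
  satisfy the anchor LSI = 1 for a landscape filled by one square class;
  the single-count convention was chosen for Fragstats equivalence.
- **SHDI** = −Σ p_i ln p_i over class proportions; **SHEI** = SHDI/ln n.
  By default all legend classes enter SHDI and n is the legend size. A
  binary profile (`n_classes=2` with a focal class) computes SHDI on
  [p, 1−p] with H_MAX = ln 2; published wetland tables are numerically
  consistent with that binary profile even when six classes were mapped,
  so multi-date reproductions should use it.

Per-patch perimeter counts every cell edge adjacent to a different class,
nodata, or the grid boundary; it is therefore an integer multiple of the
cell size and at least 4·cell_size.

### Patch-size structure

The frequency table uses interior bin edges
{10, 25, 50, 100, 300, 600, 1000, 3000, 10000} hm² (10 groups). Bins are
half-open [lo, hi): a patch of exactly 10 hm² falls in "10~25" and one of
exactly 1000 hm² in the "middle" level. The three area levels are
small < 1000 ≤ middle < 10,000 ≤ large. No minimum-mapping-unit filter is
applied by default (`min_patch_area` exposes one), so single-cell slivers
(0.09 hm² at 30 m resolution) count as patches.

Because published level/frequency tables print areas that are not exact
multiples of any cell area, `size_frequency`/`level_summary` accept plain
area lists as well as `PatchSet`s; table reproductions run on engineered
area lists.

### Change annotations

Multi-date tables annotate the first date "(\*)" and every later date with
the signed percent change versus the previous date, rounded
half-away-from-zero (Python's banker's rounding is deliberately not used).
Rounding profile for table reproduction: WP 2 d.p., LCI 3 d.p.,
PD/LSI/SHDI/SHEI 4 d.p., percent changes 1 d.p. A zero baseline yields
"n/a" rather than an annotation.

### Transfer matrices

Entry (i, j) is the area classed *i* at the first date and *j* at the
second, over cells valid in both dates; the excluded (nodata-in-either)
area is reported alongside so Σ entries + excluded = total grid area.
Rasters must be strictly comparable (same shape, cell size *and* legend);
legend drift is rejected rather than auto-merged because silent merging
corrupts transfer matrices. "Wetland to others" is the focal class's
total outflow including the grassland component — published flow tables
(outflow ≥ wetland→grassland in every interval) admit only that reading.

### Grey relational analysis

With target x₀ and factors x_i, Δ_i(k) = |x₀(k) − x_i(k)|, and Δmin/Δmax
taken globally over all factors and time points:

ε_i(k) = (Δmin + ρ·Δmax)/(Δ_i(k) + ρ·Δmax),  r_i = mean_k ε_i(k),

with resolution coefficient ρ = 0.5 by default. Ranks order r_i
descending, ties broken by input order. Since drivers are in
incommensurate units, sequences must be made dimensionless first; the
default is mean-value normalization (each series divided by its own
mean), standard GRA practice. The normalization is a logged, explicit
choice: published correlation-degree tables for the Zoige drivers cannot
be certified exactly because the normalization used there is unstated and
the underlying monthly station series were published only graphically.
Missing trailing driver years can be patched by linear extrapolation from
the two prior points (`impute_linear`), always flagged as imputed.

### Evaporation

Monthly evaporation from precipitation R (mm) and mean temperature T (°C):

E = 3100·R / (3100 + 1.8·R²·exp(−34.4·T/(235.0 + T)))

E → R as R → 0, E ≤ R, and E increases with T at fixed R > 0; the formula
is singular at T = −235 °C and rejects inputs at or below it. Annual
aggregation requires 12 months per station-year; incomplete years are
flagged and excluded from multi-station means, duplicates raise.

### Accuracy indices

Confusion matrices are oriented prediction-in-rows, reference-in-columns
(stated here because the convention varies): UA is a row property, PA a
column property, OA = trace/total, and Kappa = (p_o − p_e)/(1 − p_e) with
p_e from the marginal products. A zero marginal makes that class's UA or
PA undefined (NaN) without affecting others. Sample splitting is
stratified per class (70/30 by default) and seeded.

## Synthetic data

The generator emulates a grassland-dominated alpine plateau: six classes
(grassland 0.60, woodland 0.15, wetland 0.106, river 0.02, artificial
0.014, unused 0.11 — wetland matching the ≈10.6% observed share), default
200×200 cells of 100 m (1 hm²/cell). Landscapes grow by seeded region
growing: exact per-class cell quotas (largest remainder), random seed
cells, and weighted first-passage frontier growth where per-seed
log-normal weights (σ = 1.5) produce a long-tailed patch-size spectrum
spanning several frequency bins. Enclosed leftover cells are assigned to
classes with unmet quota, so realized proportions are exact to one cell.

Change regimes: *fragmentation* cuts 2-cell-wide corridors through large
focal patches (1-cell gaps would not disconnect an 8-connected patch) and
retries until PN strictly rises, removing only a few percent of area;
*edge-erosion* applies binary erosion (3×3 structure) so area and the
large level shrink and all transfer flow is outward; *recovery* regrows a
chosen fraction of the one-cell dilation ring and sprinkles 1–5-cell new
patches; *stationary* is the identity. A single integer seed drives every
stochastic choice; all outputs are bitwise reproducible.

What the generator does **not** emulate: spectral/radiometric content,
classification error, spatial autocorrelation of real terrain, river
sinuosity, or seasonal wetland boundaries. Passing tests therefore
establish the correctness of the metric implementations and the internal
consistency of the pipeline on realistic patch structures, not the
accuracy of any upstream classification.

Driver systems pair a smooth, positive target series with factors equal
to the target under multiplicative noise of chosen σ and arbitrary unit
scale; lower-noise factors are by construction closer in the GRA sense,
giving a known expected ranking (recovered in ≥95% of 500 replicates at
σ = {0.02, 0.3, 2.0} over 26 years).

## Numerical choices

- Half-away-from-zero rounding via `decimal` on the shortest float repr.
- SHDI input proportions must sum to 1 within 1e-9; zero entries
  contribute nothing.
- LCI inputs are validated to [0, 100].
- Patch areas are exact multiples of the cell area when derived from
  rasters; conservation checks use 1e-6 relative tolerance.
- Degenerate inputs: an all-nodata landscape raises "empty landscape"; a
  class absent from a raster yields an empty patch set (not an error);
  Δmax = 0 in GRA (all factors identical to the target) yields ε ≡ 1.

## Reproduction notes and known inconsistencies in the published record

The source rasters for the Zoige tables were never deposited, so
raster-derived numbers (PN, LSI, transfer matrices) cannot be recomputed;
desk-reproducible quantities are recomputed from the printed absolute
values. The published study area is 4,247,327 hm², but the printed PD
column implies a slightly different internal landscape area
(7093/42,473.27 km² = 0.1670 vs printed 0.1667); `area_override` exists
for exactly this situation.

Annotations recomputed from the printed absolutes reproduce the published
annotations exactly *except* where the published record contradicts
itself. Documented discrepancies (the package follows the arithmetic):

- PN 2010: printed −11.7%, arithmetic from 8403/9410 is −10.7%.
- The WA annotation column repeats the WP-derived changes: WA 2010
  printed −2.6% (arithmetic −2.7%), WA 2015 and the level-table total
  2015 printed −3.1% (arithmetic −3.0%), WA 2020 printed +2.7%
  (arithmetic +2.6%).
- Small level 2000: printed +11.0%, arithmetic +11.1%.
- Large level 2005: printed −16%, arithmetic −9.6%.
- Narrative −48.9% for small patches 2005→2015: arithmetic −48.8%.
- Binary SHDI at the printed 2020 WP (9.60) is 0.3162 vs printed 0.3177
  (≈0.5% relative); the other five dates agree within 0.13%. No single
  landscape area reconciles 2020 with the rest, so the corresponding
  acceptance test is expected to fail for 2020 and documents this.
- SHEI = SHDI/ln 2 from the *printed* (rounded) SHDI matches the printed
  SHEI to 4 d.p. for 1995/2005/2010 and differs by one final digit
  elsewhere (the published evenness was evidently computed from unrounded
  diversity values).

## Problem sizes

Default test and pipeline sizes were chosen so the whole suite exercises
realistic patch structure while staying lightweight: 200×200–300×300
synthetic landscapes (40k–90k cells, 1 hm² cells), 20×20 oracle rasters,
exhaustive 4×4 labeling enumeration (65,536 grids × 2 connectivities),
500-replicate GRA recovery runs over 26-year series. The full suite runs
in well under a minute on one CPU.

## Limitations

- Only square cells; non-square GeoTIFF pixels are rejected without an
  explicit cell-size override.
- No reprojection, resampling, mosaicking, or spectral processing —
  inputs must already be co-registered classified rasters.
- No aggregation/contagion/core-area metrics or patch-level shape indices
  beyond perimeter.
- GRA is a similarity ranking, not causal attribution; the evaporation
  formula is an empirical monthly estimator, not an energy-balance model.
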