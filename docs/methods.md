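# Methods

## Scope and data model

`wetfav` assesses favorability for wetland woody vegetation over a set of
typed wetland polygons, each tagged with a catchment and a region (north /
south). Two environmental forcings drive everything: a **bimonthly
maximum inundation depth** raster (the area of each polygon inundated
strictly deeper than 5 mm becomes the inundated-area series `A_i(t)`) and a
**daily root-zone relative soil moisture** raster (the area with moisture
in the inclusive 10–30 % band becomes the moist-area series `M_i(d)`).
Zonal extraction assigns a grid cell to a polygon iff the cell centre lies
within it (boundary inclusive), with no area-weighted fractions: this
makes a per-cell count an exact oracle for every zonal value, at the cost
of half-cell edge effects that shrink with cell size. Each raster is
processed at its native resolution; the two grids are never resampled onto
each other — within-polygon co-occurrence of inundation and moisture is
resolved by the minimum rule below, not spatially.

All downstream modelling operates on these per-polygon area series in
hectares.

## The nested-area assumption

The engine computes with polygon areas, not cell maps, so it needs a rule
for how areas at different times overlap. We assume maximal overlap:
within a polygon, the cells satisfying a condition at any two times are
subset-ordered (wetland bathymetry floods the lowest ground first and
dries it last). Under this assumption

* the area satisfying a condition **continuously** over a run of timesteps
  is the **minimum** of the per-step areas, and
* the area that **ever** satisfied it within a window is the **maximum**.

The synthetic generator enforces the assumption exactly (wet and in-band
cell sets are always prefixes of a fixed per-polygon bathymetry order), so
on generated landscapes the area engine and a brute-force per-cell
simulator must agree bit-for-bit; the test suite asserts this on 25
randomized landscapes plus the scenario library. On real rasters the
assumption is an approximation whose error grows with non-monotonic
micro-topography.

One boundary is known and documented: when the adult excess-inundation set
is neither empty nor the whole recency set at a regeneration conditioning
step, the adult-favorable cells form a rank *interval*, not a prefix, and
area arithmetic can exceed the true cell count of the downstream
intersection. Randomized validation landscapes therefore cap flood wet
durations below the adult lethal run; the lethal-run regime itself is
exercised by the `adult_drowning` scenario, where both computations
collapse to zero.

## Life-cycle engine

Three stages are chained; the adult stage is the unconditioned reference
stage (these species are long-lived and lack persistent soil seed banks,
so adults are assumed present wherever their environmental conditions are
met).

**Two-month rounding conventions.** A duration of `m` months spans
`⌈m/2⌉` bimonth steps (requirement windows round up: 4.5 months → 3
steps). Inundation within a step is treated as continuous, so a run of
`n` steps represents `2n` months and the lethal run for an excess
threshold of `m` months is the smallest `n` with `2n > m`, i.e.
`⌊m/2⌋ + 1` (a 5-month threshold needs 3 inundated steps; a 1-month
threshold makes any single inundated step lethal). Depending on the
stricture these conventions over- or under-estimate mortality; they are
applied identically across species and models, so comparisons between
model families are unaffected.

**Adults.** At step `t`: the recency term is the largest area inundated at
an in-season step within the trailing `⌈interval/2⌉`-step window (empty
in-season set → 0, not an error); the excess term is the area continuously
inundated over the lethal run ending at `t` (0 when the stricture is
absent); favorable = `max(0, recency − excess)`. The first
`max(interval_steps, run_steps)` steps are UNDEFINED: the window is
evaluated only once a full look-back plus one antecedent step exists,
which makes a 240-month interval on a January 1988 start first assessable
at the January 2008 step.

**Regeneration.** A day `d` inside the (region-resolved) germination
season is favorable over
`min(adult(s₀), min M over [d−D+1, d], A(s₀))`, where `D` is the required
consecutive moist days and `s₀` the bimonth step containing the moisture
window start — the flood that triggered germination and the step at which
the preceding adult stage is read (season membership is judged by `d`
itself, since germination completes at `d`; the moisture window may start
before the season opens). Days outside the season are 0.

**Recruitment.** For day `d` with seedling-period start `d₀ = d − P`
calendar months (fractional months at 30 days/month, so 4.5 months = 4
months + 15 days): candidate = `min(regen(d₀), min M over [d₀, d])`;
subtracted from it is the largest area continuously inundated for a lethal
run anywhere within the `⌈P/2⌉`-step window starting at the step
containing `d₀` (0 when the species has no seedling stricture, or when
the window is shorter than the run). Trailing days whose step window
extends past the inundation record are dropped rather than zeroed.

**Conditioning and strictures.** Requirement co-occurrence uses `min`
(optimistic maximal overlap); mortality strictures subtract their full
area from the candidate, floored at 0 (conservative maximal overlap).
UNDEFINED (burn-in) propagates through the chain and occupies a contiguous
prefix of every series; it is excluded from every aggregate and never
coerced to zero. A stricture with no published value is skipped entirely
and behaves as the limit of an arbitrarily large threshold.

## Species parameters

Defaults for the four species (units: days for germination moisture,
months elsewhere; `none` = stricture not applied):

| species | regen season | regen moist (d) | seedling moist (mo) | seedling excess (mo) | adult excess (mo) | adult interval (mo) | adult season |
|---|---|---|---|---|---|---|---|
| red gum | Sep–Dec | 14 | 4.5 | 2 | 24 | 48 | Jul–Dec |
| black box | May–Oct (N), Nov–Mar (S) | 10 | 6 | 2 | 5 | 96 | year-round |
| coolabah | Jan–Apr | 14 | 6 | none | none | 240 | year-round |
| lignum | Sep–Apr | 14 | 3 | 1 | 12 | 120 | Sep–Dec |

Threshold phrases of the form "more than *m* months" are stored as `m`
with the strict-exceedance run rule above ("several months" → 2, "any
inundation" → 1). Coolabah's missing strictures very likely overestimate
its seedling survival. Regional season variants resolve through each
polygon's region tag. A bimonth step is in-season if its two calendar
months overlap the window.

## Habitat models and comparison statistics

The *named* set scans type descriptions for configurable species aliases,
case-insensitively. The *recorded* set joins point records to polygons
(boundary-inclusive; ties to the smallest polygon), counts records per
wetland type, and keeps types holding strictly more than 0.5 % of the
records; all polygons of a kept type are retained, not only those with a
record. The share denominator defaults to records that matched any
polygon — unmatched records carry no type information — with the
all-records denominator available as an option. Duplicate records all
count.

Per-polygon series are averaged over the water year (July 1 – June 30,
labelled by starting year); a year is defined only if every native
timestep is covered and defined. A yearly-maximum variant is available as
a sensitivity option. Totals sum polygons over catchments or the basin in
native hectares. Percent reduction is `100 (1 − restricted/unrestricted)`;
overlap proportion is `combined / process`; overlap classes use a float
tolerance of 10⁻⁶ ha: `nested` when combined equals process, `none` when
combined is zero while both families found area, `partial` between, `na`
for degenerate inputs. Reported percentages round to the nearest integer,
except sub-1 % values to one decimal.

## Synthetic generator

The generator emulates the structural features the analysis relies on —
not hydrological realism (no rainfall-runoff, routing, or climate
emulation):

* rectangular polygons tiled on a shared grid (1 ha cells by default, so
  areas equal cell counts), typed from a weighted palette whose
  descriptions embed species names, grouped into catchments and regions,
  each with a random strict bathymetry order over its cells;
* flood events as instant rise to a peak flooded fraction, optional
  plateau, then linear recession of the flooded prefix; depths are 6 mm
  plus a rank increment so the >5 mm rule selects exactly the flooded set;
* soil moisture saturated while flooded, then — once an event's water has
  fully receded — a drying curve shared by every cell the event inundated
  at peak: a linear ramp from saturation (0.9) to the band ceiling (0.30)
  over `entry_days` (default 3), then exponential decay at rate
  `ln 3 / band_days`, keeping the soil in the 10–30 % band for
  `band_days` days before settling at the 0.05 baseline. The shared clock
  is what keeps the in-band set a bathymetry prefix; a physically staggered
  per-cell clock would make it a rank interval and void the exactness the
  oracle tests require. Events whose drying windows would overlap within a
  polygon are rejected, unless an event is explicitly decoupled from the
  moisture model (a surface-water pulse that does not reset root-zone
  drying) — the device scenarios use to isolate the inundation stricture;
* Gaussian noise only on never-flooded cells, clipped below the band floor
  so it can never flip a membership decision;
* occurrence records with per-polygon Poisson counts scaled by type
  intensity, or exact per-type counts for threshold engineering.

Fixtures are emitted both as rasters and as zonal series computed directly
from the constructed prefix sizes, so the engine is testable with and
without the geometry path. Everything is reproducible from the scenario
seed. Passing tests on these fixtures demonstrate the engine's arithmetic
and sequencing, not predictive skill on real landscapes, where nesting is
approximate, moisture drying is spatially staggered, and polygons are not
rectangles.

The five scripted scenarios encode the life-cycle rules as narratives:
`textbook_recruitment` (recruitment exactly in the designed water year,
over the designed flood prefix), `drowned_seedlings` (a re-flood inside
the seedling window kills lignum but leaves stricture-free coolabah
bit-for-bit unchanged, via a moisture-decoupled pulse), `senescent_stand`
(named habitat inundated but process-unfavorable while processes succeed
elsewhere: combined zero, class `none`), `expansion_front` (processes
favorable only outside habitat types: overlap proportion zero), and
`adult_drowning` (a lethal continuous-inundation run zeroes the adult
stage exactly while the run is complete).

## Numerical choices

* UNDEFINED is NaN; the engine guarantees it forms a contiguous prefix.
* Bimonth blocks are calendar-aligned Jan–Feb, Mar–Apr, … by default, with
  a configurable anchor month, since the alignment of real source layers
  varies by product.
* Degenerate inputs: a polygon wholly outside the raster extent is an
  error listing the offending ids; a partially off-grid polygon
  contributes zero for the off-grid portion with a warning (strict mode
  errors); a series shorter than the burn-in warns and returns all
  UNDEFINED; zero denominators in reduction/overlap statistics return
  not-applicable (NaN), never infinities.
* Occurrence joins resolve multi-polygon ties to the smallest area;
  tolerance for overlap classification is 10⁻⁶ ha; engine comparisons in
  tests demand exact equality because generated areas are integer cell
  counts.

## Design choices and limitations

* **Monotonicity.** Raising or removing an excess threshold, lengthening
  the adult interval, and widening a season are provably monotone through
  the stage chain, and a 1,000-perturbation audit asserts this. The
  moisture durations (`D`, `P`) are excluded: shortening them moves the
  window start and hence the conditioning step/day, so outputs at a fixed
  day are not comparable — a shorter `D` can move the window start out of
  the triggering flood's step and legitimately reduce regeneration.
* The adult look-back for regeneration reads the step containing the
  moisture-window start; an optional extra step of look-back is a
  configuration hook for window-spanning starts.
* The framework interprets the adult→regeneration→recruitment sequence as
  conditions favorable for recruitment, not as population dynamics: no
  demography, dispersal, competition, or temperature strictures.
* Habitat sets are static in time; records are used as-is with no survey
  bias correction or deduplication.
* No raster reprojection or resampling; CRS labels are checked for
  equality only.
* Full-scale runs over national rasters and hundreds of thousands of
  polygons are out of scope here; the zonal mapper is linear in cells ×
  timesteps and the engine in polygons × timesteps, so nothing in the
  design precludes them, but I/O adapters for the real products (cloud
  GeoTIFF stacks, product-specific NetCDF layouts) are left to the user.
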