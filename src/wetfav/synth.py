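"""Synthetic landscapes, environmental rasters, occurrence records, scenarios.

The generator emulates the structure the analysis assumes so that every
stage is testable without external downloads:

* a mosaic of typed, catchment- and region-tagged rectangular wetland
  polygons tiled on a shared grid, each with a strict bathymetry rank over
  its cells (lowest ground floods first);
* bimonthly depth grids whose within-polygon inundated cell sets are
  bathymetry **prefixes** at every step, hence exactly nested through time;
* daily soil-moisture grids with saturation during flooding and a shared
  post-event drying curve (short ramp to 30 %, then exponential decay
  through the 10-30 % band), so the in-band cell set is also always a
  bathymetry prefix;
* point occurrence records with type-biased intensities.

Because wet and in-band cell sets are always prefixes of one fixed order,
run minima and window maxima of areas equal continuously- and
ever-satisfying areas exactly, and a brute-force per-cell simulator
reproduces the area engine cell-for-cell.  The drying clock is shared by
all cells an event inundated at its peak (a per-cell staggered clock would
turn the in-band set into a rank interval and break this exactness); events
whose drying windows would overlap within a polygon are rejected unless the
later event is marked moisture-decoupled (a surface-water pulse that does
not reset root-zone drying — used by scenarios that isolate the
inundation stricture).

Fixtures are emitted both as rasters (exercising zonal ingestion) and as
zonal series computed directly from the constructed prefix sizes
(exercising the engine in isolation).  Cells default to 1 ha so areas equal
cell counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .core import BIMONTHLY, DAILY, RasterSeries, Wetlands, WetlandPolygon, ZonalSeries
from .habitat import TypeCatalog
from .timeutil import bimonth_range

__all__ = [
    "FloodEvent",
    "MoistureModel",
    "ScenarioSpec",
    "Landscape",
    "Fixture",
    "gen_landscape",
    "gen_inundation",
    "gen_soil_moisture",
    "gen_occurrences",
    "scenario_library",
    "random_scenario",
    "write_fixture",
]

# wetland types named for dominant vegetation, as in a national aquatic
# ecosystem classification; weights are palette sampling probabilities
DEFAULT_PALETTE: tuple[tuple[str, str, float], ...] = (
    ("red_gum_forest", "River red gum forest riparian zone or floodplain", 0.15),
    ("red_gum_woodland", "River red gum woodland riparian zone or floodplain", 0.10),
    ("red_gum_swamp", "Temporary river red gum swamp", 0.10),
    ("black_box_woodland", "Black box woodland riparian zone or floodplain", 0.15),
    ("lignum_swamp", "Temporary lignum swamp or shrubland", 0.10),
    ("coolabah_woodland", "Coolabah woodland riparian zone or floodplain", 0.10),
    ("permanent_lake", "Permanent lake", 0.10),
    ("temporary_wetland", "Temporary freshwater wetland or marsh", 0.20,),
)


@dataclasses.dataclass(frozen=True)
class FloodEvent:
    """One flood pulse: instant rise to a peak flooded fraction, an optional
    plateau, then linear recession of the flooded prefix.

    ``end_offset_days`` places the moment the water fully recedes (the start
    of the shared drying clock) that many days into the last wet step, so
    the triggering step is both inundated and adjacent to the moist window.
    ``moisture_coupled=False`` makes the event invisible to the soil-moisture
    model.
    """

    start_step: int
    peak_frac: float
    hold_steps: int = 0
    recession_steps: int = 0
    end_offset_days: int = 20
    moisture_coupled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_frac <= 1.0:
            raise ValueError("peak_frac must be in [0, 1]")
        if self.recession_steps < 0 or self.hold_steps < 0:
            raise ValueError("hold/recession steps must be >= 0")

    @property
    def last_wet_step(self) -> int:
        return self.start_step + self.hold_steps + self.recession_steps

    def wet_fraction(self, step: int) -> float:
        if step < self.start_step or step > self.last_wet_step:
            return 0.0
        j = step - self.start_step - self.hold_steps
        if j <= 0:
            return self.peak_frac
        return self.peak_frac * (1.0 - j / (self.recession_steps + 1.0))


@dataclasses.dataclass(frozen=True)
class MoistureModel:
    """Post-flood drying curve for the root zone.

    Saturated while flooded; after the shared drying clock starts, a linear
    ramp from ``saturation`` down to the band ceiling (0.30) over
    ``entry_days``, then exponential decay with rate ``ln(3)/band_days`` so
    the moisture stays inside the 10-30 % band for ``band_days`` days.
    Never-flooded cells sit at ``baseline`` plus bounded noise kept strictly
    below the band floor (noise never flips band membership).
    """

    saturation: float = 0.9
    entry_days: int = 3
    band_days: float = 170.0
    baseline: float = 0.05
    noise_sd: float = 0.01

    @property
    def decay_rate(self) -> float:
        return math.log(3.0) / self.band_days

    def profile(self, n_days: int) -> np.ndarray:
        """Moisture value for each integer day since the drying clock start."""
        tau = np.arange(n_days, dtype=float)
        ramp = self.saturation - (self.saturation - 0.30) * tau / self.entry_days
        decay = 0.30 * np.exp(-self.decay_rate * (tau - self.entry_days))
        m = np.where(tau < self.entry_days, ramp, decay)
        return np.maximum(m, self.baseline)

    def dry_after_days(self) -> int:
        """Days from clock start until the cell has left the band for good."""
        return int(math.ceil(self.entry_days + self.band_days)) + 1


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """Reproducible specification of a synthetic landscape and its forcing."""

    seed: int = 0
    n_polygons: int = 6
    poly_shape: tuple[int, int] = (10, 10)  # cells (nx, ny) per polygon
    cell_size: float = 100.0  # metres; 100 m -> 1 ha cells
    type_palette: tuple[tuple[str, str, float], ...] = DEFAULT_PALETTE
    types_override: "tuple[str, ...] | None" = None  # explicit type per polygon
    n_catchments: int = 2
    start: str = "1996-07-01"
    years: int = 10
    events: "Mapping[str, tuple[FloodEvent, ...]] | tuple[FloodEvent, ...]" = ()
    moisture: MoistureModel = MoistureModel()
    crs: str = "synthetic-planar"

    def events_for(self, polygon_id: str) -> tuple[FloodEvent, ...]:
        if isinstance(self.events, Mapping):
            return tuple(self.events.get(polygon_id, ()))
        return tuple(self.events)


@dataclasses.dataclass
class Landscape:
    """Generated polygons plus the shared grid and bathymetry order."""

    spec: ScenarioSpec
    wetlands: Wetlands
    catalog: TypeCatalog
    nx: int
    ny: int
    cell_order: dict[str, np.ndarray]  # pid -> flat cell indices, deepest first
    steps: pd.DatetimeIndex
    days: pd.DatetimeIndex

    @property
    def cell_area_ha(self) -> float:
        return self.spec.cell_size ** 2 / 1e4

    def n_cells(self, pid: str) -> int:
        return self.cell_order[pid].size

    def wet_counts(self) -> pd.DataFrame:
        """Exact wet-prefix cell counts (step x polygon) from the event envelopes."""
        out = {}
        for pid in self.wetlands.polygon_ids:
            n = self.n_cells(pid)
            fracs = np.zeros(len(self.steps))
            for ev in self.spec.events_for(pid):
                f = np.array([ev.wet_fraction(s) for s in range(len(self.steps))])
                fracs = np.maximum(fracs, f)
            out[pid] = np.rint(fracs * n).astype(int)
        return pd.DataFrame(out, index=self.steps)

    def clock_start_day(self, ev: FloodEvent) -> int:
        """Day index at which the shared drying clock of ``ev`` starts."""
        step_start = self.steps[min(ev.last_wet_step, len(self.steps) - 1)]
        return int((step_start - self.days[0]).days) + ev.end_offset_days

    def flood_start_day(self, ev: FloodEvent) -> int:
        return int((self.steps[ev.start_step] - self.days[0]).days)


def gen_landscape(spec: ScenarioSpec) -> Landscape:
    if spec.n_polygons < 1:
        raise ValueError("n_polygons must be >= 1")
    rng = np.random.default_rng(spec.seed)
    pw, ph = spec.poly_shape
    ncols = math.ceil(math.sqrt(spec.n_polygons))
    nrows = math.ceil(spec.n_polygons / ncols)
    nx, ny = ncols * pw, nrows * ph
    cs = spec.cell_size

    palette_types = [t for t, _, _ in spec.type_palette]
    weights = np.array([w for _, _, w in spec.type_palette], dtype=float)
    weights = weights / weights.sum()
    if spec.types_override is not None:
        if len(spec.types_override) != spec.n_polygons:
            raise ValueError("types_override must list one type per polygon")
        chosen = list(spec.types_override)
    else:
        chosen = list(rng.choice(palette_types, size=spec.n_polygons, p=weights))
    descriptions = {t: d for t, d, _ in spec.type_palette}

    polys, cell_order = [], {}
    for i in range(spec.n_polygons):
        r, c = divmod(i, ncols)
        pid = f"w{i:03d}"
        geom = shapely.box(c * pw * cs, r * ph * cs, (c + 1) * pw * cs, (r + 1) * ph * cs)
        wtype = chosen[i]
        polys.append(
            WetlandPolygon(
                polygon_id=pid,
                geometry=geom,
                wetland_type=wtype,
                type_description=descriptions.get(wtype, wtype),
                area_ha=pw * ph * cs * cs / 1e4,
                catchment=f"catch-{i % spec.n_catchments}",
                region="north" if r < nrows / 2 else "south",
            )
        )
        rows = np.arange(r * ph, (r + 1) * ph)
        cols = np.arange(c * pw, (c + 1) * pw)
        flat = (rows[:, None] * nx + cols[None, :]).ravel()
        cell_order[pid] = rng.permutation(flat)

    wetlands = Wetlands.from_polygons(polys, crs=spec.crs)
    catalog = TypeCatalog({t: d for t, d, _ in spec.type_palette})
    start = pd.Timestamp(spec.start)
    steps = bimonth_range(start, spec.years * 6)
    days = pd.date_range(start, start + pd.DateOffset(years=spec.years) - pd.Timedelta(days=1))
    return Landscape(spec, wetlands, catalog, nx, ny, cell_order, steps, days)


def _coords(land: Landscape) -> dict:
    cs = land.spec.cell_size
    return {
        "x": (np.arange(land.nx) + 0.5) * cs,
        "y": (np.arange(land.ny) + 0.5) * cs,
    }


def gen_inundation(land: Landscape) -> RasterSeries:
    """Bimonthly maximum-depth raster; wet cells are exactly the bathymetry
    prefix of each polygon's wet count, at depths strictly above 5 mm."""
    counts = land.wet_counts()
    grid = np.zeros((len(land.steps), land.ny * land.nx), dtype=np.float32)
    for pid, order in land.cell_order.items():
        k = counts[pid].to_numpy()
        for t in range(len(land.steps)):
            if k[t] > 0:
                wet = order[: k[t]]
                # deepest (rank 0) gets the greatest depth; all exceed 5 mm
                grid[t, wet] = 6.0 + 0.1 * (k[t] - 1 - np.arange(k[t]))
    da = xr.DataArray(
        grid.reshape(len(land.steps), land.ny, land.nx),
        dims=("time", "y", "x"),
        coords={"time": land.steps, **_coords(land)},
    )
    return RasterSeries(da, variable="depth_mm", resolution=BIMONTHLY,
                        cell_size=land.spec.cell_size, crs=land.spec.crs)


def _check_spacing(land: Landscape, events: Sequence[FloodEvent]) -> None:
    coupled = sorted((e for e in events if e.moisture_coupled), key=lambda e: e.start_step)
    dry_gap = land.spec.moisture.dry_after_days()
    for prev, nxt in zip(coupled, coupled[1:]):
        if land.flood_start_day(nxt) <= land.clock_start_day(prev) + dry_gap:
            raise ValueError(
                f"moisture-coupled events at steps {prev.start_step} and {nxt.start_step} "
                "have overlapping drying windows; separate them or decouple one"
            )


def gen_soil_moisture(land: Landscape, rng: "np.random.Generator | None" = None) -> RasterSeries:
    """Daily soil-moisture raster with the shared post-event drying clock."""
    mm = land.spec.moisture
    n_days = len(land.days)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([land.spec.seed, 7]))
    grid = np.full((n_days, land.ny * land.nx), mm.baseline, dtype=np.float64)
    profile = mm.profile(n_days)
    for pid, order in land.cell_order.items():
        events = land.spec.events_for(pid)
        _check_spacing(land, events)
        coupled = sorted((e for e in events if e.moisture_coupled), key=lambda e: e.start_step)
        flooded_any = np.zeros(land.n_cells(pid), dtype=bool)
        for ev in coupled:
            k = int(round(ev.peak_frac * land.n_cells(pid)))
            if k == 0:
                continue
            cells = order[:k]
            flooded_any[:k] = True
            f0 = max(land.flood_start_day(ev), 0)
            c0 = land.clock_start_day(ev)
            sat_end = min(c0, n_days)
            if f0 < sat_end:
                grid[f0:sat_end, cells] = mm.saturation
            if c0 < n_days:
                c0 = max(c0, 0)
                grid[c0:, cells] = profile[: n_days - c0, None]
        if mm.noise_sd > 0 and (~flooded_any).any():
            quiet = order[~flooded_any]
            noise = rng.normal(0.0, mm.noise_sd, size=(n_days, quiet.size))
            grid[:, quiet] = np.clip(mm.baseline + noise, 0.0, 0.08)
    # kept float64: the drying curve touches the band edges exactly, and the
    # exact zonal series must agree with the raster bit-for-bit
    da = xr.DataArray(
        grid.reshape(n_days, land.ny, land.nx),
        dims=("time", "y", "x"),
        coords={"time": land.days, **_coords(land)},
    )
    return RasterSeries(da, variable="moisture_fraction", resolution=DAILY,
                        cell_size=land.spec.cell_size, crs=land.spec.crs)


def exact_inundation_zonal(land: Landscape, depth_threshold_mm: float = 5.0) -> ZonalSeries:
    """Inundated-area zonal series from the constructed prefix sizes (no geometry)."""
    counts = land.wet_counts()
    df = counts.astype(float) * land.cell_area_ha
    df.columns = df.columns.astype(str)
    return ZonalSeries(df, resolution=BIMONTHLY, variable="inundated_area")


def exact_moisture_zonal(land: Landscape, band=(0.10, 0.30)) -> ZonalSeries:
    """In-band-area zonal series from the drying-curve values (no geometry).

    Evaluates the same per-day moisture values the raster holds (in float64,
    before the raster's float32 cast) for each event's peak prefix and
    thresholds them, so raster-derived and exact series agree.
    """
    mm = land.spec.moisture
    n_days = len(land.days)
    profile = mm.profile(n_days)
    out = {}
    for pid in land.wetlands.polygon_ids:
        events = [e for e in land.spec.events_for(pid) if e.moisture_coupled]
        events.sort(key=lambda e: e.start_step)
        n = land.n_cells(pid)
        # per-cell-rank last applicable event timeline, vectorised by prefix:
        # later events override ranks < their peak from their flood start
        owner = np.full((n_days, n), -1, dtype=int)
        for idx, ev in enumerate(events):
            k = int(round(ev.peak_frac * n))
            f0 = max(land.flood_start_day(ev), 0)
            if k > 0 and f0 < n_days:
                owner[f0:, :k] = idx
        counts = np.zeros(n_days, dtype=int)
        for idx, ev in enumerate(events):
            c0 = land.clock_start_day(ev)
            dday = np.arange(n_days)
            tau = dday - c0
            m = np.full(n_days, np.nan)
            sat = (dday >= max(land.flood_start_day(ev), 0)) & (tau < 0)
            m[sat] = mm.saturation
            dec = tau >= 0
            m[dec] = profile[tau[dec]]
            in_band = (m >= band[0]) & (m <= band[1])
            counts += in_band * (owner == idx).sum(axis=1)
        out[pid] = counts * land.cell_area_ha
    df = pd.DataFrame(out, index=land.days)
    df.columns = df.columns.astype(str)
    return ZonalSeries(df, resolution=DAILY, variable="moist_area")


def gen_occurrences(
    wetlands: Wetlands,
    intensities: Mapping[str, float],
    seed: int = 0,
    species: str = "species",
    exact_counts: "Mapping[str, int] | None" = None,
) -> pd.DataFrame:
    """Point records with type-biased intensities.

    Per-polygon counts are Poisson with mean ``intensities[wetland_type]``
    (0 for unlisted types); points are uniform within the polygon.
    ``exact_counts`` instead fixes the total record count per type
    (distributed round-robin over that type's polygons), for engineering
    record shares that straddle a selection threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    frame = wetlands.frame
    if exact_counts is not None:
        counts = pd.Series(0, index=frame.index)
        for wtype, total in exact_counts.items():
            pids = frame.index[frame["wetland_type"] == wtype]
            if len(pids) == 0:
                raise ValueError(f"no polygons of type {wtype!r}")
            for j in range(total):
                counts[pids[j % len(pids)]] += 1
    else:
        lam = frame["wetland_type"].map(lambda t: intensities.get(t, 0.0)).astype(float)
        counts = pd.Series(rng.poisson(lam.to_numpy()), index=frame.index)
    for pid, n in counts.items():
        if n == 0:
            continue
        geom = frame.loc[pid, "geometry"]
        minx, miny, maxx, maxy = geom.bounds
        got = 0
        while got < n:
            xs = rng.uniform(minx, maxx, size=n - got)
            ys = rng.uniform(miny, maxy, size=n - got)
            ok = shapely.intersects_xy(geom, xs, ys)
            for x, y in zip(xs[ok], ys[ok]):
                rows.append({"species": species, "x": x, "y": y})
            got += int(ok.sum())
    return pd.DataFrame(rows, columns=["species", "x", "y"])


# ---------------------------------------------------------------------------
# scenario library


@dataclasses.dataclass
class Fixture:
    """A built scenario: landscape, rasters, exact zonal series, ground truth."""

    name: str
    species: str
    landscape: Landscape
    inundation_raster: RasterSeries
    moisture_raster: RasterSeries
    inundation: ZonalSeries
    moisture: ZonalSeries
    truth: dict
    companion: "Fixture | None" = None  # e.g. the no-re-flood baseline variant


@dataclasses.dataclass(frozen=True)
class Scenario:
    name: str
    species: str
    description: str
    builder: Callable[[], Fixture]

    def build(self) -> Fixture:
        return self.builder()


def _build_fixture(spec: ScenarioSpec, name: str, species: str, truth: dict,
                   rasters: bool = True) -> Fixture:
    land = gen_landscape(spec)
    inund_r = gen_inundation(land) if rasters else None
    moist_r = gen_soil_moisture(land) if rasters else None
    return Fixture(
        name=name,
        species=species,
        landscape=land,
        inundation_raster=inund_r,
        moisture_raster=moist_r,
        inundation=exact_inundation_zonal(land),
        moisture=exact_moisture_zonal(land),
        truth=truth,
    )


def _textbook_recruitment() -> Fixture:
    # One spring flood after the adult burn-in; drying keeps soil in band
    # through the seedling period; no re-flood.  Recruitment succeeds only
    # in the designed water year, over the flood's peak prefix.
    peak = 0.6
    spec = ScenarioSpec(
        seed=11,
        n_polygons=4,
        poly_shape=(8, 8),
        types_override=("red_gum_forest", "red_gum_swamp", "temporary_wetland", "permanent_lake"),
        start="1996-07-01",
        years=7,
        events=(FloodEvent(start_step=31, peak_frac=peak),),  # Sep-Oct 2001
        moisture=MoistureModel(band_days=170.0),
    )
    truth = {
        "designed_water_year": 2001,
        "peak_fraction": peak,
        "recruitment_area_per_polygon_ha": {f"w{i:03d}": peak * 64 for i in range(4)},
    }
    return _build_fixture(spec, "textbook_recruitment", "red_gum", truth)


def _drowned_seedlings() -> Fixture:
    # An adult-enabling spring flood (moisture-decoupled), a summer
    # germination pulse, and - in the primary variant - a re-flood inside
    # the seedling window, decoupled from soil moisture so it isolates the
    # inundation stricture.  Lignum seedlings die with any inundated step in
    # the window; coolabah has no seedling stricture and is unchanged.
    peak = 0.6
    common = dict(
        seed=13,
        n_polygons=4,
        poly_shape=(8, 8),
        types_override=("lignum_swamp", "coolabah_woodland", "temporary_wetland", "permanent_lake"),
        start="1982-07-01",
        years=23,
        moisture=MoistureModel(band_days=200.0),
    )
    f1 = FloodEvent(start_step=127, peak_frac=peak, moisture_coupled=False)  # Sep-Oct 2003
    f2 = FloodEvent(start_step=129, peak_frac=peak)                          # Jan-Feb 2004
    f3 = FloodEvent(start_step=131, peak_frac=peak, moisture_coupled=False)  # May-Jun 2004
    truth = {"designed_water_year": 2003, "peak_fraction": peak}
    primary = _build_fixture(
        ScenarioSpec(events=(f1, f2, f3), **common), "drowned_seedlings", "lignum", truth
    )
    primary.companion = _build_fixture(
        ScenarioSpec(events=(f1, f2), **common), "drowned_seedlings_baseline", "lignum", truth
    )
    return primary


_SENESCENT_TYPES = ("red_gum_forest", "red_gum_woodland", "red_gum_swamp",
                    "temporary_wetland", "permanent_lake", "temporary_wetland")


def _habitat_process_split(name: str, flood_named: bool) -> Fixture:
    # Named red-gum polygons are (optionally) inundated out of season, so
    # habitat models score them while processes never do; plain wetlands get
    # textbook spring floods, so recruitment succeeds only outside the named
    # types.  Combined favorability is therefore zero.
    peak = 0.5
    events: dict[str, tuple[FloodEvent, ...]] = {}
    for i in range(3):  # named polygons: autumn floods in designed years
        if flood_named:
            events[f"w{i:03d}"] = (
                FloodEvent(start_step=34, peak_frac=peak),  # Mar-Apr 2002
                FloodEvent(start_step=40, peak_frac=peak),  # Mar-Apr 2003
            )
    for i in range(3, 6):  # plain wetlands: spring floods -> recruitment
        events[f"w{i:03d}"] = (
            FloodEvent(start_step=31, peak_frac=peak),  # Sep-Oct 2001
            FloodEvent(start_step=37, peak_frac=peak),  # Sep-Oct 2002
        )
    spec = ScenarioSpec(
        seed=17,
        n_polygons=6,
        poly_shape=(8, 8),
        types_override=_SENESCENT_TYPES,
        start="1996-07-01",
        years=8,
        events=events,
        moisture=MoistureModel(band_days=170.0),
    )
    truth = {"designed_water_years": [2001, 2002], "peak_fraction": peak}
    return _build_fixture(spec, name, "red_gum", truth)


def _adult_drowning() -> Fixture:
    # Continuous full-polygon inundation for longer than the adult excess
    # threshold: favorability collapses to zero once the lethal run
    # completes, and recovers when the run breaks.
    spec = ScenarioSpec(
        seed=19,
        n_polygons=2,
        poly_shape=(8, 8),
        types_override=("red_gum_forest", "temporary_wetland"),
        start="1996-07-01",
        years=9,
        events=(FloodEvent(start_step=25, peak_frac=1.0, hold_steps=14),),  # wet steps 25..39
        moisture=MoistureModel(band_days=60.0),
    )
    truth = {"wet_steps": [25, 39], "lethal_from_step": 37}
    return _build_fixture(spec, "adult_drowning", "red_gum", truth)


def scenario_library() -> dict[str, Scenario]:
    """Named ground-truth scenarios encoding the life-cycle rules as narratives."""
    return {
        "textbook_recruitment": Scenario(
            "textbook_recruitment", "red_gum",
            "in-season flood, sustained moisture, no re-flood: recruitment "
            "succeeds exactly in the designed water year",
            _textbook_recruitment,
        ),
        "drowned_seedlings": Scenario(
            "drowned_seedlings", "lignum",
            "re-flood inside the seedling window kills lignum seedlings but "
            "leaves coolabah (no stricture) unchanged",
            _drowned_seedlings,
        ),
        "senescent_stand": Scenario(
            "senescent_stand", "red_gum",
            "named habitat inundated but process-unfavorable while processes "
            "succeed elsewhere: combined favorability zero, overlap class none",
            lambda: _habitat_process_split("senescent_stand", flood_named=True),
        ),
        "expansion_front": Scenario(
            "expansion_front", "red_gum",
            "processes favorable only outside the habitat types: overlap "
            "proportion zero",
            lambda: _habitat_process_split("expansion_front", flood_named=False),
        ),
        "adult_drowning": Scenario(
            "adult_drowning", "red_gum",
            "continuous inundation beyond the adult excess threshold drives "
            "adult favorability to zero",
            _adult_drowning,
        ),
    }


def random_scenario(seed: int, species: str = "red_gum") -> Fixture:
    """A randomized small landscape for oracle-equivalence testing.

    Flood wet durations are capped below the species' adult lethal run so
    the adult excess set stays empty at conditioning steps (the regime in
    which area arithmetic and cell counting agree exactly; the lethal-run
    regime is covered by the adult_drowning scenario).
    """
    rng = np.random.default_rng(seed)
    n_poly = int(rng.integers(4, 13))
    pw = int(rng.integers(4, 8))
    max_wet = {"red_gum": 5, "black_box": 2, "lignum": 5, "coolabah": 6}[species]
    mm = MoistureModel(band_days=float(rng.integers(40, 201)),
                       entry_days=int(rng.integers(2, 6)),
                       noise_sd=0.01)
    n_steps = 60  # 10 years
    spec0 = ScenarioSpec(seed=seed, n_polygons=n_poly, poly_shape=(pw, pw),
                         start="1996-07-01", years=10, moisture=mm)
    land0 = gen_landscape(spec0)
    events: dict[str, tuple[FloodEvent, ...]] = {}
    for pid in land0.wetlands.polygon_ids:
        evs: list[FloodEvent] = []
        step = int(rng.integers(0, 20))
        while step < n_steps - 2:
            hold = int(rng.integers(0, max_wet))
            rec = int(rng.integers(0, max(1, max_wet - hold)))
            ev = FloodEvent(
                start_step=step,
                peak_frac=float(rng.uniform(0.2, 1.0)),
                hold_steps=hold,
                recession_steps=rec,
                end_offset_days=int(rng.integers(5, 45)),
            )
            if ev.last_wet_step >= n_steps:
                break
            evs.append(ev)
            # enforce drying-window spacing before the next flood
            gap_days = mm.dry_after_days() + 40 + ev.end_offset_days
            step = ev.last_wet_step + 1 + math.ceil(gap_days / 61) + int(rng.integers(0, 6))
        events[pid] = tuple(evs)
    spec = dataclasses.replace(spec0, events=events)
    return _build_fixture(spec, f"random-{seed}", species, truth={})


def write_fixture(fixture: Fixture, out_dir: "str | Path") -> None:
    """Persist a fixture: GeoJSON polygons, NetCDF rasters, CSV zonal series,
    and a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture.landscape.wetlands.to_geojson(out / "polygons.geojson")
    if fixture.inundation_raster is not None:
        fixture.inundation_raster.to_netcdf(out / "inundation.nc")
    if fixture.moisture_raster is not None:
        fixture.moisture_raster.to_netcdf(out / "moisture.nc")
    fixture.inundation.to_csv(out / "inundation_zonal.csv")
    fixture.moisture.to_csv(out / "moisture_zonal.csv")
    manifest = {
        "name": fixture.name,
        "species": fixture.species,
        "seed": fixture.landscape.spec.seed,
        "truth": fixture.truth,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
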