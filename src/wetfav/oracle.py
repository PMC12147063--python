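"""Brute-force per-cell simulator used to validate the area-based engine.

Tracks each grid cell's wet / moisture-band state through time and applies
the life-cycle rules cell-wise, then counts favorable cells per polygon.
On landscapes whose wet and in-band cell sets are bathymetry prefixes
(which the synthetic generator guarantees), these counts must equal the
polygon-area engine's output exactly, stage for stage and step for step.

The implementation is deliberately direct — explicit windows over boolean
cell states — and shares no code path with the engine's rolling-window area
arithmetic.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from .core import RasterSeries, Wetlands
from .requirements import SpeciesRequirements

__all__ = ["simulate_cells"]


def _cells_by_polygon(raster: RasterSeries, wetlands: Wetlands) -> dict[str, np.ndarray]:
    xs, ys = raster.cell_centers()
    return {
        str(pid): np.nonzero(shapely.intersects_xy(geom, xs, ys))[0]
        for pid, geom in wetlands.geometries.items()
    }


def _season_months(season) -> "frozenset[int] | None":
    return None if season is None else season.months


def _step_of(dates, origin: pd.Timestamp) -> np.ndarray:
    dates = pd.DatetimeIndex(dates)
    m0 = origin.year * 12 + origin.month - 1
    m = dates.year.to_numpy() * 12 + dates.month.to_numpy() - 1
    return (m - m0) // 2


def simulate_cells(
    inundation_raster: RasterSeries,
    moisture_raster: RasterSeries,
    wetlands: Wetlands,
    reqs: SpeciesRequirements,
    habitat_types: "frozenset[str] | None" = None,
    depth_threshold_mm: float = 5.0,
    band: tuple[float, float] = (0.10, 0.30),
    cells: "Mapping[str, np.ndarray] | None" = None,
) -> dict[str, pd.DataFrame]:
    """Cell-wise favorability areas for every stage (and habitat/combined
    models if ``habitat_types`` is given).  NaN marks burn-in."""
    steps = inundation_raster.times
    days = moisture_raster.times
    wet = inundation_raster.data.values.reshape(len(steps), -1) > depth_threshold_mm
    m = moisture_raster.data.values.reshape(len(days), -1)
    inband = (m >= band[0]) & (m <= band[1])
    n_steps, n_cells = wet.shape
    n_days = len(days)
    if cells is None:
        cells = _cells_by_polygon(inundation_raster, wetlands)
    pids = [str(p) for p in wetlands.polygon_ids]
    regions = wetlands.frame["region"]
    cell_area = inundation_raster.cell_area_ha

    # per-cell region-dependent season masks
    cell_region = np.empty(n_cells, dtype=object)
    for pid in pids:
        cell_region[cells[pid]] = regions[pid]

    def step_in_season(which: str) -> np.ndarray:
        out = np.zeros((n_steps, n_cells), dtype=bool)
        block_months = [(t.month, t.month % 12 + 1) for t in steps]
        for region in set(cell_region[np.concatenate([cells[p] for p in pids])]):
            season = reqs.resolve_season(which, region)
            months = _season_months(season)
            sel = cell_region == region
            for t, (m1, m2) in enumerate(block_months):
                ok = months is None or m1 in months or m2 in months
                out[t, sel] = ok
        return out

    def day_in_season(which: str) -> np.ndarray:
        out = np.zeros((n_days, n_cells), dtype=bool)
        day_months = days.month.to_numpy()
        for region in set(cell_region[np.concatenate([cells[p] for p in pids])]):
            season = reqs.resolve_season(which, region)
            months = _season_months(season)
            sel = cell_region == region
            ok = (
                np.ones(n_days, dtype=bool)
                if months is None
                else np.isin(day_months, list(months))
            )
            out[np.ix_(ok, sel)] = True
        return out

    # ---- adults ----------------------------------------------------------
    W = math.ceil(reqs.adult_inundation_interval_months / 2.0)
    E = reqs.adult_excess_inundation_months
    R = math.floor(E / 2.0) + 1 if E is not None else None
    burn = max(W, R or 0)
    season_wet = wet & step_in_season("adult_inundation_season")
    adult_ok = np.zeros((n_steps, n_cells), dtype=bool)
    for t in range(burn, n_steps):
        recency = season_wet[t - W + 1 : t + 1].any(axis=0)
        drowned = wet[t - R + 1 : t + 1].all(axis=0) if R is not None else False
        adult_ok[t] = recency & ~drowned

    # ---- regeneration ----------------------------------------------------
    D = int(reqs.regeneration_moisture_days)
    run_ok = np.zeros((n_days, n_cells), dtype=bool)
    view = np.lib.stride_tricks.sliding_window_view(inband, D, axis=0)
    run_ok[D - 1 :] = view.all(axis=-1)
    start_days = days - pd.Timedelta(days=D - 1)
    s0 = _step_of(start_days, steps[0])
    s0_valid = (s0 >= 0) & (s0 < n_steps)
    regen_ok = np.zeros((n_days, n_cells), dtype=bool)
    rows = np.nonzero(s0_valid)[0]
    regen_ok[rows] = run_ok[rows] & wet[s0[rows]] & adult_ok[s0[rows]]
    regen_ok &= day_in_season("regeneration_season")
    ok_rows = s0_valid & (s0 >= burn) & (np.arange(n_days) >= D - 1)
    regen_cut = int(np.nonzero(ok_rows)[0][0]) if ok_rows.any() else n_days

    # ---- recruitment -----------------------------------------------------
    P = float(reqs.seedling_moisture_months)
    whole = math.floor(P)
    d0 = days - pd.DateOffset(months=whole) - pd.Timedelta(days=round((P - whole) * 30))
    d0 = pd.DatetimeIndex(d0)
    i0 = (d0 - days[0]).days.to_numpy()
    i0_valid = i0 >= 0
    # continuously in band over [d0, d]: the most recent dry day is before d0
    day_idx = np.arange(n_days)[:, None]
    last_dry = np.maximum.accumulate(np.where(~inband, day_idx, -1), axis=0)
    SE = reqs.seedling_excess_inundation_months
    Wp = math.ceil(P / 2.0)
    sp0 = _step_of(d0, steps[0])
    end_step = sp0 + Wp - 1
    killed = np.zeros((n_days, n_cells), dtype=bool)
    if SE is not None:
        Rs = math.floor(SE / 2.0) + 1
        if Wp >= Rs:
            wet_run = np.zeros((n_steps, n_cells), dtype=bool)
            wview = np.lib.stride_tricks.sliding_window_view(wet, Rs, axis=0)
            wet_run[Rs - 1 :] = wview.all(axis=-1)
            for s in np.unique(sp0):
                if s < 0 or s + Wp - 1 >= n_steps:
                    continue
                rows = np.nonzero(sp0 == s)[0]
                killed[rows] = wet_run[max(s + Rs - 1, 0) : s + Wp].any(axis=0)
    recruit_ok = np.zeros((n_days, n_cells), dtype=bool)
    rows = np.nonzero(i0_valid)[0]
    recruit_ok[rows] = (
        regen_ok[i0[rows]] & (last_dry[rows] < i0[rows, None]) & ~killed[rows]
    )
    ok_rows = i0_valid & (i0 >= regen_cut)
    recruit_cut = int(np.nonzero(ok_rows)[0][0]) if ok_rows.any() else n_days
    keep = end_step <= n_steps - 1

    # ---- counts -> areas -------------------------------------------------
    def areas(ok: np.ndarray, index, cut: int) -> pd.DataFrame:
        df = pd.DataFrame(
            {pid: ok[:, cells[pid]].sum(axis=1) * cell_area for pid in pids},
            index=index,
            dtype=float,
        )
        df.iloc[:cut] = np.nan
        return df

    out = {
        "adult": areas(adult_ok, steps, burn),
        "regeneration": areas(regen_ok, days, regen_cut),
        "recruitment": areas(recruit_ok, days, recruit_cut).loc[keep],
    }
    if habitat_types is not None:
        in_set = np.zeros(n_cells, dtype=bool)
        for pid in pids:
            if wetlands.frame.loc[pid, "wetland_type"] in habitat_types:
                in_set[cells[pid]] = True
        out["habitat"] = areas(wet & in_set, steps, 0)
        out["combined"] = areas(recruit_ok & in_set, days, recruit_cut).loc[keep]
    return out
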