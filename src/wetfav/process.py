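"""The strictures life-cycle engine.

Computes per-polygon favorable area for three stages in sequence — adults
(the unconditioned reference stage), regeneration (germination/sprouting,
conditioned on adults), and recruitment (seedling survival, conditioned on
regeneration) — from bimonthly inundated-area and daily moist-area zonal
series plus a species' threshold requirements.

Area arithmetic rests on the nested-area assumption: within a polygon, the
areas satisfying a condition at different times overlap maximally (lowest
ground floods first), so the minimum over a run of timesteps is the area
continuously satisfying the condition and the maximum over a window is the
area that ever satisfied it.  Stage conditioning uses the minimum rule: a
stage's favorable area is capped by the preceding stage's area at the
stage's start.  Mortality strictures (excessive continuous inundation) are
subtracted in full from the candidate area, floored at zero.

Two-month rounding conventions: a duration of ``m`` months spans
``ceil(m / 2)`` bimonth steps (requirement windows round up), while a run of
``n`` inundated steps is treated as ``2 n`` continuous months, so the lethal
run length for an excess threshold of ``m`` months is the smallest ``n``
with ``2 n > m``, i.e. ``floor(m / 2) + 1``.

Leading timesteps whose look-back windows are incomplete are UNDEFINED
(NaN), never zero; they form a contiguous prefix of every series and are
excluded from all aggregates.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .core import BIMONTHLY, DAILY, StageSeries, Wetlands, ZonalSeries
from .requirements import SpeciesRequirements
from .timeutil import Season, bimonth_index_of, shift_months

__all__ = [
    "months_to_steps",
    "excess_run_steps",
    "continuous_inundation_area",
    "sustained_moisture_area",
    "conditional_min",
    "adult_favorability",
    "regeneration_favorability",
    "recruitment_favorability",
    "run_process_model",
]


def months_to_steps(months: float) -> int:
    """Bimonth steps spanning a duration of ``months``, rounded up.

    e.g. a 4.5-month requirement occupies 3 steps (6 months).
    """
    if months <= 0:
        raise ValueError("months must be positive")
    return math.ceil(months / 2.0)


def excess_run_steps(excess_months: float) -> int:
    """Lethal run length in steps for an excess-inundation threshold.

    Inundation within a step is assumed continuous, so a run of ``n`` steps
    is ``2 n`` months; lethality needs the smallest ``n`` with
    ``2 n > excess_months``.  A 5-month threshold needs 3 inundated steps; a
    1-month threshold makes any single inundated step lethal.
    """
    if excess_months <= 0:
        raise ValueError("excess_months must be positive")
    return math.floor(excess_months / 2.0) + 1


def conditional_min(preceding_area_at_start, target_area):
    """Minimum rule for stage conditioning; UNDEFINED (NaN) propagates."""
    return np.minimum(preceding_area_at_start, target_area)


def _loc_index(series: ZonalSeries, timestep) -> int:
    try:
        return int(series.times.get_loc(pd.Timestamp(timestep)))
    except KeyError:
        raise KeyError(f"timestep {timestep} not in series") from None


def continuous_inundation_area(
    inundation: ZonalSeries, polygon_id: str, end_step, run_steps: int
) -> float:
    """Area inundated throughout the run of ``run_steps`` steps ending at ``end_step``.

    Under the nested-area assumption this is the minimum inundated area over
    the run.  Returns NaN (UNDEFINED) if the run extends before the series.
    """
    i = end_step if isinstance(end_step, (int, np.integer)) else _loc_index(inundation, end_step)
    if run_steps <= 0:
        raise ValueError("run_steps must be positive")
    if i - run_steps + 1 < 0:
        return float("nan")
    col = inundation.data[str(polygon_id)].to_numpy()
    return float(col[i - run_steps + 1 : i + 1].min())


def sustained_moisture_area(
    moisture: ZonalSeries, polygon_id: str, end_day, days: int
) -> float:
    """Area continuously in the moisture band over the ``days``-long window ending at ``end_day``."""
    i = end_day if isinstance(end_day, (int, np.integer)) else _loc_index(moisture, end_day)
    if days <= 0:
        raise ValueError("days must be positive")
    if i - days + 1 < 0:
        return float("nan")
    col = moisture.data[str(polygon_id)].to_numpy()
    return float(col[i - days + 1 : i + 1].min())


def _season_mask_by_polygon(
    months: np.ndarray,
    reqs: SpeciesRequirements,
    which: str,
    wetlands: Wetlands,
    polygon_ids: pd.Index,
    per_block: bool,
) -> np.ndarray:
    """(T, P) in-season mask; ``per_block`` uses 2-month block overlap, else the
    calendar month itself.  A ``None`` season means year-round."""
    regions = wetlands.frame["region"].reindex(polygon_ids)
    if regions.isna().any():
        missing = regions.index[regions.isna()].tolist()
        raise KeyError(f"polygons absent from wetland set: {missing}")
    out = np.empty((len(months), len(polygon_ids)), dtype=bool)
    for region in regions.unique():
        season = reqs.resolve_season(which, region)
        cols = (regions == region).to_numpy()
        if season is None:
            mask = np.ones(len(months), dtype=bool)
        elif per_block:
            mask = season.overlaps_block(months)
        else:
            mask = season.contains_month(months)
        out[:, cols] = mask[:, None]
    return out


def adult_favorability(
    inundation: ZonalSeries, reqs: SpeciesRequirements, wetlands: Wetlands
) -> StageSeries:
    """Bimonthly adult favorable area.

    At each step the favorable area is the largest area inundated during an
    in-season step within the trailing interval window, minus the area
    continuously inundated beyond the excess threshold (if that stricture
    exists), floored at zero.  Steps without a full look-back are UNDEFINED.
    """
    if inundation.resolution != BIMONTHLY:
        raise ValueError("adult stage requires a bimonthly inundation series")
    V = inundation.data
    W = months_to_steps(reqs.adult_inundation_interval_months)
    E = reqs.adult_excess_inundation_months
    R = excess_run_steps(E) if E is not None else None
    burn = max(W, R or 0)
    months = inundation.times.month.to_numpy()
    in_season = _season_mask_by_polygon(
        months, reqs, "adult_inundation_season", wetlands, V.columns, per_block=True
    )
    masked = V.where(pd.DataFrame(in_season, index=V.index, columns=V.columns), 0.0)
    recency = masked.rolling(W, min_periods=W).max()
    if R is not None:
        excess = V.rolling(R, min_periods=R).min()
        fav = (recency - excess).clip(lower=0.0)
    else:
        fav = recency
    if burn >= len(V):
        warnings.warn(
            f"{reqs.species}: series of {len(V)} steps is shorter than the "
            f"{burn}-step adult burn-in; all steps UNDEFINED",
            stacklevel=2,
        )
    fav.iloc[:burn] = np.nan
    return StageSeries(fav, resolution=BIMONTHLY, stage="adult", model="process")


def _first_defined_row(stage: StageSeries) -> "int | None":
    notna = stage.data.notna().all(axis=1).to_numpy()
    idx = np.nonzero(notna)[0]
    return int(idx[0]) if idx.size else None


def _check_daily(moisture: ZonalSeries) -> pd.DatetimeIndex:
    days = moisture.times
    if moisture.resolution != DAILY:
        raise ValueError("moisture series must be daily")
    return days


def regeneration_favorability(
    adult: StageSeries,
    inundation: ZonalSeries,
    moisture: ZonalSeries,
    reqs: SpeciesRequirements,
    wetlands: Wetlands,
) -> StageSeries:
    """Daily regeneration favorable area, conditioned on adults.

    A day ``d`` inside the (region-resolved) regeneration season is
    favorable over the area where soil moisture stayed in band for the
    preceding ``regeneration_moisture_days`` days, the polygon was inundated
    in the bimonth step containing the start of that moisture window (the
    triggering flood), and adults were favorable at that step.  Days outside
    the season are zero; days whose look-back reaches into the adult burn-in
    are UNDEFINED.
    """
    days = _check_daily(moisture)
    if not adult.times.equals(inundation.times):
        raise ValueError("adult series must share the inundation step index")
    D = int(reqs.regeneration_moisture_days)
    M = moisture.data
    cols = M.columns
    mmin = M.rolling(D, min_periods=D).min().to_numpy()

    start_days = days - pd.Timedelta(days=D - 1)
    s0 = bimonth_index_of(start_days, origin=inundation.times[0])
    n_steps = len(inundation.times)
    if s0[-1] >= n_steps:
        raise ValueError("inundation series ends before the moisture series")
    valid = s0 >= 0

    adult_np = adult.data[cols].to_numpy()
    inund_np = inundation.data[cols].to_numpy()
    A0 = np.full((len(days), len(cols)), np.nan)
    I0 = np.full_like(A0, np.nan)
    A0[valid] = adult_np[s0[valid]]
    I0[valid] = inund_np[s0[valid]]

    raw = np.minimum(np.minimum(A0, mmin), I0)
    in_season = _season_mask_by_polygon(
        days.month.to_numpy(), reqs, "regeneration_season", wetlands, cols, per_block=False
    )
    out = np.where(in_season, raw, 0.0)

    adult_first = _first_defined_row(adult)
    if adult_first is None:
        cutoff = len(days)
    else:
        ok = valid & (s0 >= adult_first) & (np.arange(len(days)) >= D - 1)
        nz = np.nonzero(ok)[0]
        cutoff = int(nz[0]) if nz.size else len(days)
    out[:cutoff] = np.nan
    frame = pd.DataFrame(out, index=days, columns=cols)
    return StageSeries(frame, resolution=DAILY, stage="regeneration", model="process")


def recruitment_favorability(
    regeneration: StageSeries,
    inundation: ZonalSeries,
    moisture: ZonalSeries,
    reqs: SpeciesRequirements,
    wetlands: Wetlands,
) -> StageSeries:
    """Daily recruitment (seedling survival) favorable area.

    For day ``d`` with seedling period start ``d0 = d - P`` calendar months:
    the candidate area is the minimum of regeneration at ``d0`` and the area
    continuously in the moisture band over ``[d0, d]``; the area continuously
    inundated for a lethal run of bimonth steps anywhere inside the
    ``ceil(P / 2)``-step window covering the seedling period (rounded up to
    whole bimonths) is then subtracted, floored at zero.  Days whose step
    window extends past the inundation series are dropped; days reaching into
    the regeneration burn-in are UNDEFINED.
    """
    days = _check_daily(moisture)
    if not regeneration.times.equals(days):
        raise ValueError("regeneration series must share the moisture day index")
    P = float(reqs.seedling_moisture_months)
    cols = moisture.data.columns
    M = moisture.data
    n_days, n_poly = len(days), len(cols)

    d0 = shift_months(days, -P)
    i0 = (d0 - days[0]).days.to_numpy()
    i = np.arange(n_days)
    valid = i0 >= 0
    L = i - i0 + 1

    wmin = np.full((n_days, n_poly), np.nan)
    for length in np.unique(L[valid]):
        rows = valid & (L == length)
        r = M.rolling(int(length), min_periods=int(length)).min().to_numpy()
        wmin[rows] = r[rows]

    regen_np = regeneration.data[cols].to_numpy()
    R0 = np.full((n_days, n_poly), np.nan)
    R0[valid] = regen_np[i0[valid]]

    E = reqs.seedling_excess_inundation_months
    Wp = months_to_steps(P)
    sp0 = bimonth_index_of(d0, origin=inundation.times[0])
    end_step = sp0 + Wp - 1
    n_steps = len(inundation.times)
    # trim trailing days whose step window is not yet observable
    keep = end_step <= n_steps - 1
    excess = np.zeros((n_days, n_poly))
    if E is not None:
        Rs = excess_run_steps(E)
        if Wp >= Rs:
            V = inundation.data[cols]
            runmin = V.rolling(Rs, min_periods=Rs).min()
            q = runmin.rolling(Wp - Rs + 1, min_periods=Wp - Rs + 1).max().to_numpy()
            rows = valid & keep & (end_step >= 0)
            excess[rows] = q[end_step[rows]]
        # a window shorter than the lethal run cannot contain one: excess 0

    out = np.clip(np.minimum(R0, wmin) - excess, 0.0, None)

    regen_first = _first_defined_row(regeneration)
    if regen_first is None:
        cutoff = n_days
    else:
        ok = valid & (i0 >= regen_first)
        nz = np.nonzero(ok)[0]
        cutoff = int(nz[0]) if nz.size else n_days
    out[:cutoff] = np.nan
    frame = pd.DataFrame(out, index=days, columns=cols).loc[keep]
    return StageSeries(frame, resolution=DAILY, stage="recruitment", model="process")


def run_process_model(
    inundation: ZonalSeries,
    moisture: ZonalSeries,
    reqs: SpeciesRequirements,
    wetlands: Wetlands,
) -> dict[str, StageSeries]:
    """Chain the three stages: adults -> regeneration -> recruitment."""
    adult = adult_favorability(inundation, reqs, wetlands)
    regen = regeneration_favorability(adult, inundation, moisture, reqs, wetlands)
    recruit = recruitment_favorability(regen, inundation, moisture, reqs, wetlands)
    return {"adult": adult, "regeneration": regen, "recruitment": recruit}
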