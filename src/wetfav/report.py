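"""Combined models, water-year/catchment/basin aggregation, overlap statistics.

The combined model masks a process-stage series to a habitat set's wetland
types; because favorable cells must satisfy both model families, its totals
measure the spatial overlap between habitat- and process-based favorability.
Per-polygon series are averaged over the water year (July 1 - June 30,
labelled by starting year) and summed over catchments or the whole basin,
in native hectares throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BIMONTHLY, StageSeries, Wetlands
from .habitat import HabitatSet
from .timeutil import water_year_of

__all__ = [
    "combined_favorability",
    "water_year_mean",
    "spatial_sum",
    "period_mean",
    "percent_reduction",
    "overlap_proportion",
    "classify_overlap",
    "overlap_records",
    "round_percent",
    "OVERLAP_TOL_HA",
]

OVERLAP_TOL_HA = 1e-6


def combined_favorability(
    process: StageSeries, habitat: HabitatSet, wetlands: Wetlands
) -> StageSeries:
    """Process-stage favorability zeroed outside the habitat set's types.

    UNDEFINED (burn-in) entries are preserved, not zeroed.
    """
    types = wetlands.type_of().reindex(process.polygon_ids)
    if types.isna().any():
        missing = types.index[types.isna()].tolist()
        raise KeyError(f"polygons absent from wetland set: {missing}")
    if habitat.method == "all":
        member = pd.Series(True, index=process.polygon_ids)
    else:
        member = types.isin(habitat.types)
    keep = np.broadcast_to(member.to_numpy(), process.data.shape) | process.data.isna().to_numpy()
    data = process.data.where(pd.DataFrame(keep, index=process.data.index, columns=process.data.columns), 0.0)
    return StageSeries(
        data,
        resolution=process.resolution,
        stage="combined",
        model=f"combined:{process.stage}:{habitat.method}",
    )


def water_year_mean(series: StageSeries, statistic: str = "mean") -> pd.DataFrame:
    """Per-polygon annual values: mean (or max) over each water year.

    A water year is defined only if the series covers every native timestep
    of that year (6 bimonth steps, or each calendar day) with a defined
    value; otherwise it is UNDEFINED (NaN).  ``statistic="max"`` gives the
    yearly-maximum sensitivity variant.
    """
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    wy = water_year_of(series.times)
    grouped = series.data.groupby(wy)
    agg = grouped.max() if statistic == "max" else grouped.mean()
    # skipna is not configurable through groupby aggregates: redo NaN rule
    counts = series.data.notna().groupby(wy).sum()
    expected = pd.Series(
        {
            y: 6
            if series.resolution == BIMONTHLY
            else (pd.Timestamp(y + 1, 7, 1) - pd.Timestamp(y, 7, 1)).days
            for y in counts.index
        }
    )
    complete = counts.eq(expected, axis=0)
    agg = agg.where(complete)
    agg.index.name = "water_year"
    return agg


def spatial_sum(annual: pd.DataFrame, wetlands: Wetlands, unit: str = "basin") -> pd.DataFrame:
    """Tidy totals per spatial unit and water year, in hectares.

    ``unit`` is ``"basin"`` (one total) or ``"catchment"``.  UNDEFINED years
    propagate (a unit-year is NaN if any member polygon-year is NaN, which
    only happens during burn-in when all are).
    """
    if unit not in ("basin", "catchment"):
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "basin":
        groups = pd.Series("basin", index=annual.columns)
    else:
        groups = wetlands.frame["catchment"].reindex(annual.columns)
        if groups.isna().any():
            missing = groups.index[groups.isna()].tolist()
            raise KeyError(f"polygons absent from wetland set: {missing}")
    totals = annual.T.groupby(groups.to_numpy()).sum(min_count=0)
    # NaN propagation: sum() skips NaN; mask unit-years with any NaN member
    has_nan = annual.isna().T.groupby(groups.to_numpy()).any()
    totals = totals.where(~has_nan)
    long = totals.T.stack(future_stack=True).rename("total_area_ha").reset_index()
    long.columns = ["water_year", "unit", "total_area_ha"]
    return long[["unit", "water_year", "total_area_ha"]]


def period_mean(summary: pd.DataFrame) -> pd.Series:
    """Mean total per unit over the defined (post-burn-in) water years."""
    return summary.dropna(subset=["total_area_ha"]).groupby("unit")["total_area_ha"].mean()


def percent_reduction(unrestricted_ha: float, restricted_ha: float) -> float:
    """Percent loss going from an unrestricted to a restricted model.

    NaN (not applicable) if the unrestricted total is zero.
    """
    if unrestricted_ha == 0 or np.isnan(unrestricted_ha):
        return float("nan")
    return 100.0 * (1.0 - restricted_ha / unrestricted_ha)


def overlap_proportion(combined_total: float, process_total: float) -> float:
    """Fraction of process-favorable area that is also habitat-favorable."""
    if process_total == 0 or np.isnan(process_total):
        return float("nan")
    return combined_total / process_total


def classify_overlap(
    habitat_total: float,
    process_total: float,
    combined_total: float,
    tol: float = OVERLAP_TOL_HA,
) -> str:
    """Spatial-overlap class for one water year.

    * ``nested`` - all process-favorable area lies within the habitat types
      (combined equals process, to tolerance);
    * ``none`` - both model families find favorable area but in disjoint
      wetlands (combined is zero);
    * ``partial`` - some, but not all, process-favorable area is inside;
    * ``na`` - degenerate (a model family found nothing, or burn-in).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if any(np.isnan(v) for v in (habitat_total, process_total, combined_total)):
        return "na"
    if process_total > 0 and abs(combined_total - process_total) <= tol:
        return "nested"
    if combined_total <= tol and habitat_total > tol and process_total > tol:
        return "none"
    if tol < combined_total < process_total - tol:
        return "partial"
    return "na"


def overlap_records(
    habitat_summary: pd.DataFrame,
    process_summary: pd.DataFrame,
    combined_summary: pd.DataFrame,
    tol: float = OVERLAP_TOL_HA,
) -> pd.DataFrame:
    """Per-water-year overlap table for one spatial unit set.

    Inputs are ``spatial_sum`` outputs for the habitat model, the process
    model, and their combination.
    """
    def series(df, name):
        return df.set_index(["unit", "water_year"])["total_area_ha"].rename(name)

    merged = pd.concat(
        [
            series(habitat_summary, "habitat_total"),
            series(process_summary, "process_total"),
            series(combined_summary, "combined_total"),
        ],
        axis=1,
    ).reset_index()
    merged["class"] = [
        classify_overlap(h, p, c, tol=tol)
        for h, p, c in zip(
            merged["habitat_total"], merged["process_total"], merged["combined_total"]
        )
    ]
    return merged


def round_percent(pct: float) -> float:
    """Reporting convention: nearest integer, except sub-1 % to one decimal."""
    if np.isnan(pct):
        return float("nan")
    if abs(pct) < 1.0:
        return round(pct, 1)
    return float(round(pct))
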