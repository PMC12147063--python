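"""Life-history threshold parameters for the process-based model.

Each species carries the inundation and soil-moisture requirements used by
the strictures-and-promoters life-cycle engine:

* ``regeneration_season`` - month window in which germination/sprouting can
  complete (may differ by Basin region, resolved via each polygon's region
  tag);
* ``regeneration_moisture_days`` - consecutive days of in-band soil moisture
  required for germination;
* ``seedling_moisture_months`` - months of sustained in-band moisture for
  seedling survival (may be fractional, e.g. 4.5);
* ``seedling_excess_inundation_months`` - continuous inundation longer than
  this kills seedlings (``None`` = no stricture applied, i.e. no information
  is available and seedlings are modelled as surviving any inundation);
* ``adult_excess_inundation_months`` - likewise for adults;
* ``adult_inundation_interval_months`` - adults remain favorable while the
  last qualifying inundation is at most this old;
* ``adult_inundation_season`` - window in which inundation counts toward the
  adult requirement (``None`` = year-round).

Defaults ship for the four Murray-Darling Basin species modelled: river red
gum, black box, coolabah and lignum.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import yaml

from .timeutil import Season

__all__ = ["SpeciesRequirements", "SPECIES_REQUIREMENTS", "load_requirements", "dump_requirements"]

SeasonSpec = "Season | Mapping[str, Season] | None"


@dataclasses.dataclass(frozen=True)
class SpeciesRequirements:
    species: str
    regeneration_season: "Season | Mapping[str, Season]"
    regeneration_moisture_days: int
    seedling_moisture_months: float
    seedling_excess_inundation_months: float | None
    adult_excess_inundation_months: float | None
    adult_inundation_interval_months: float
    adult_inundation_season: "Season | Mapping[str, Season] | None" = None

    def __post_init__(self) -> None:
        if self.regeneration_moisture_days <= 0:
            raise ValueError("regeneration_moisture_days must be positive")
        if self.seedling_moisture_months <= 0:
            raise ValueError("seedling_moisture_months must be positive")
        if self.adult_inundation_interval_months <= 0:
            raise ValueError("adult_inundation_interval_months must be positive")
        for name in ("seedling_excess_inundation_months", "adult_excess_inundation_months"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive or None")

    def resolve_season(self, which: str, region: str) -> "Season | None":
        """Region-resolved season window; ``None`` means year-round."""
        season = getattr(self, which)
        if season is None or isinstance(season, Season):
            return season
        try:
            return season[region]
        except KeyError:
            raise KeyError(
                f"{self.species}: no {which} entry for region {region!r} "
                f"(have {sorted(season)})"
            ) from None


SPECIES_REQUIREMENTS: dict[str, SpeciesRequirements] = {
    # River red gum (Eucalyptus camaldulensis): spring-early summer
    # germination; "several months" of seedling inundation kills (stored as
    # the >2-month exceedance rule); adults drown after 24 months continuous
    # inundation and need winter-early summer flooding at least every 4 years.
    "red_gum": SpeciesRequirements(
        species="red_gum",
        regeneration_season=Season(9, 12),
        regeneration_moisture_days=14,
        seedling_moisture_months=4.5,
        seedling_excess_inundation_months=2.0,
        adult_excess_inundation_months=24.0,
        adult_inundation_interval_months=48.0,
        adult_inundation_season=Season(7, 12),
    ),
    # Black box (Eucalyptus largiflorens): regeneration season differs
    # between the northern and southern Basin; adults tolerate only ~5 months
    # continuous inundation but need flooding just once in 8 years.
    "black_box": SpeciesRequirements(
        species="black_box",
        regeneration_season={"north": Season(5, 10), "south": Season(11, 3)},
        regeneration_moisture_days=10,
        seedling_moisture_months=6.0,
        seedling_excess_inundation_months=2.0,
        adult_excess_inundation_months=5.0,
        adult_inundation_interval_months=96.0,
        adult_inundation_season=None,
    ),
    # Coolabah (Eucalyptus coolabah): late-summer germination; no published
    # excess-inundation limits, so no strictures are applied (this very
    # likely overestimates seedling survival); adults need flooding only
    # once in 20 years.
    "coolabah": SpeciesRequirements(
        species="coolabah",
        regeneration_season=Season(1, 4),
        regeneration_moisture_days=14,
        seedling_moisture_months=6.0,
        seedling_excess_inundation_months=None,
        adult_excess_inundation_months=None,
        adult_inundation_interval_months=240.0,
        adult_inundation_season=None,
    ),
    # Lignum (Duma florulenta): spring-autumn sprouting; any inundation
    # during the seedling period kills (stored as the >1-month rule, i.e. a
    # single inundated bimonth step is lethal); short 3-month seedling
    # moisture period.
    "lignum": SpeciesRequirements(
        species="lignum",
        regeneration_season=Season(9, 4),
        regeneration_moisture_days=14,
        seedling_moisture_months=3.0,
        seedling_excess_inundation_months=1.0,
        adult_excess_inundation_months=12.0,
        adult_inundation_interval_months=120.0,
        adult_inundation_season=Season(9, 12),
    ),
}


def _season_to_obj(season):
    if season is None:
        return None
    if isinstance(season, Season):
        return [season.start_month, season.end_month]
    return {region: [s.start_month, s.end_month] for region, s in season.items()}


def _season_from_obj(obj):
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {region: Season(*pair) for region, pair in obj.items()}
    return Season(*obj)


def dump_requirements(reqs: SpeciesRequirements, path: "str | Path") -> None:
    doc = {
        "species": reqs.species,
        "regeneration_season": _season_to_obj(reqs.regeneration_season),
        "regeneration_moisture_days": reqs.regeneration_moisture_days,
        "seedling_moisture_months": reqs.seedling_moisture_months,
        "seedling_excess_inundation_months": reqs.seedling_excess_inundation_months,
        "adult_excess_inundation_months": reqs.adult_excess_inundation_months,
        "adult_inundation_interval_months": reqs.adult_inundation_interval_months,
        "adult_inundation_season": _season_to_obj(reqs.adult_inundation_season),
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_requirements(path: "str | Path") -> SpeciesRequirements:
    doc = yaml.safe_load(Path(path).read_text())
    return SpeciesRequirements(
        species=doc["species"],
        regeneration_season=_season_from_obj(doc["regeneration_season"]),
        regeneration_moisture_days=int(doc["regeneration_moisture_days"]),
        seedling_moisture_months=float(doc["seedling_moisture_months"]),
        seedling_excess_inundation_months=(
            None
            if doc.get("seedling_excess_inundation_months") is None
            else float(doc["seedling_excess_inundation_months"])
        ),
        adult_excess_inundation_months=(
            None
            if doc.get("adult_excess_inundation_months") is None
            else float(doc["adult_excess_inundation_months"])
        ),
        adult_inundation_interval_months=float(doc["adult_inundation_interval_months"]),
        adult_inundation_season=_season_from_obj(doc.get("adult_inundation_season")),
    )
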