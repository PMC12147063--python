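"""Habitat-based favorability: wetland-type sets and inundation masking.

Two habitat definitions per species, on top of the overarching "all
wetlands" filter:

* **named** - wetland types whose free-text description contains the
  species' name (any configured alias, case-insensitive);
* **recorded** - wetland types holding strictly more than a minimum share
  (default 0.5 %) of the species' occurrence records, after joining point
  records to polygons; all polygons of an identified type are retained, not
  just those containing a record.

Habitat-based favorability is then simply the inundated area of each
polygon, zeroed unless the polygon's type is in the set.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .core import StageSeries, Wetlands, ZonalSeries

__all__ = [
    "TypeCatalog",
    "HabitatSet",
    "named_types",
    "recorded_types",
    "habitat_favorability",
    "join_records",
    "read_occurrences",
    "DEFAULT_ALIASES",
    "MIN_RECORD_SHARE",
]

MIN_RECORD_SHARE = 0.005

# Default name aliases used to scan wetland-type descriptions.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "red_gum": ("river red gum", "red gum"),
    "black_box": ("black box",),
    "coolabah": ("coolabah",),
    "lignum": ("lignum",),
}


class TypeCatalog:
    """Mapping wetland_type -> description text."""

    def __init__(self, entries: dict[str, str]):
        if not entries:
            raise ValueError("empty type catalog")
        for t, d in entries.items():
            if not str(d).strip():
                raise ValueError(f"empty description for wetland type {t!r}")
        self.entries = {str(t): str(d) for t, d in entries.items()}

    @classmethod
    def from_wetlands(cls, wetlands: Wetlands) -> "TypeCatalog":
        frame = wetlands.frame
        entries: dict[str, str] = {}
        for t, d in zip(frame["wetland_type"], frame["type_description"]):
            desc = str(d).strip() or str(t)
            entries.setdefault(str(t), desc)
        return cls(entries)

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.entries)

    def __contains__(self, wetland_type: str) -> bool:
        return wetland_type in self.entries


@dataclasses.dataclass(frozen=True)
class HabitatSet:
    """A species' habitat definition: a set of wetland types under one method."""

    species: str
    method: str  # all | named | recorded
    types: frozenset[str]

    def __post_init__(self) -> None:
        if self.method not in ("all", "named", "recorded"):
            raise ValueError(f"unknown habitat method {self.method!r}")

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(
            json.dumps(
                {"species": self.species, "method": self.method, "types": sorted(self.types)}
            )
        )

    @classmethod
    def from_json(cls, path: "str | Path") -> "HabitatSet":
        doc = json.loads(Path(path).read_text())
        return cls(doc["species"], doc["method"], frozenset(doc["types"]))


def all_types(catalog: TypeCatalog, species: str) -> HabitatSet:
    """The overarching filter: every wetland type in the catalog."""
    return HabitatSet(species, "all", catalog.types)


def named_types(catalog: TypeCatalog, species: str, aliases=None) -> HabitatSet:
    """Types whose description contains any species alias, case-insensitively."""
    if aliases is None:
        aliases = DEFAULT_ALIASES.get(species)
    if not aliases:
        raise ValueError(f"no name aliases given for species {species!r}")
    lowered = [a.lower() for a in aliases]
    hits = {
        t for t, desc in catalog.entries.items() if any(a in desc.lower() for a in lowered)
    }
    return HabitatSet(species, "named", frozenset(hits))


def read_occurrences(path: "str | Path") -> pd.DataFrame:
    """Occurrence records CSV with columns species, x, y (planar CRS)."""
    df = pd.read_csv(path)
    missing = {"species", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return df


def join_records(records: pd.DataFrame, wetlands: Wetlands) -> pd.Series:
    """Point-in-polygon join: polygon_id per record (NaN if in no polygon).

    Boundary points join; a point falling in several overlapping polygons is
    assigned to the smallest-area polygon.
    """
    xs = np.asarray(records["x"], dtype=float)
    ys = np.asarray(records["y"], dtype=float)
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("occurrence records contain non-finite coordinates")
    geoms = wetlands.geometries.to_numpy()
    areas = wetlands.area_ha().to_numpy()
    ids = wetlands.polygon_ids.to_numpy()
    tree = STRtree(geoms)
    pts = shapely.points(xs, ys)
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    out = np.full(len(records), None, dtype=object)
    best_area = np.full(len(records), np.inf)
    for i, j in zip(pt_idx, poly_idx):
        if areas[j] < best_area[i]:
            best_area[i] = areas[j]
            out[i] = ids[j]
    return pd.Series(out, index=records.index, name="polygon_id")


def recorded_types(
    records: pd.DataFrame,
    wetlands: Wetlands,
    catalog: TypeCatalog,
    species: str,
    min_share: float = MIN_RECORD_SHARE,
    denominator: str = "matched",
) -> HabitatSet:
    """Types with strictly more than ``min_share`` of the species' records.

    ``denominator`` is ``"matched"`` (records that fell inside any wetland
    polygon; default, since unmatched records carry no type information) or
    ``"all"`` (every record supplied).  Duplicate records all count.
    """
    if denominator not in ("matched", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    joined = join_records(records, wetlands)
    matched = joined.dropna()
    if matched.empty:
        warnings.warn(
            f"no {species} records fall inside any wetland polygon; recorded set is empty",
            stacklevel=2,
        )
        return HabitatSet(species, "recorded", frozenset())
    types = wetlands.type_of().reindex(matched.to_numpy()).to_numpy()
    counts = pd.Series(types).value_counts()
    total = len(matched) if denominator == "matched" else len(records)
    share = counts / total
    kept = frozenset(share.index[share > min_share].astype(str))
    return HabitatSet(species, "recorded", kept)


def habitat_favorability(
    inundation: ZonalSeries,
    habitat: HabitatSet,
    wetlands: Wetlands,
    catalog: "TypeCatalog | None" = None,
) -> StageSeries:
    """Inundated area, zeroed outside the habitat set's wetland types.

    With ``method="all"`` this is an exact pass-through of the inundation
    series (every polygon's type is in the set).  If a ``catalog`` is given,
    a polygon whose type is absent from it is an error.
    """
    types = wetlands.type_of().reindex(inundation.polygon_ids)
    if types.isna().any():
        missing = types.index[types.isna()].tolist()
        raise KeyError(f"polygons absent from wetland set: {missing}")
    if catalog is not None:
        unknown = sorted(set(types) - catalog.types)
        if unknown:
            raise KeyError(f"wetland types missing from catalog: {unknown}")
    if habitat.method == "all":
        member = pd.Series(True, index=inundation.polygon_ids)
    else:
        member = types.isin(habitat.types)
    keep = np.broadcast_to(member.to_numpy(), inundation.data.shape)
    data = inundation.data.where(
        pd.DataFrame(keep, index=inundation.data.index, columns=inundation.data.columns), 0.0
    )
    return StageSeries(
        data,
        resolution=inundation.resolution,
        stage="habitat",
        model=f"habitat:{habitat.method}",
    )
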