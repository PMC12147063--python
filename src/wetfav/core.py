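"""Core containers: wetland polygons, raster time series, zonal time series.

The package works at two levels: gridded environmental rasters (depth,
soil-moisture fraction) and per-polygon area time series ("zonal series")
derived from them.  All model logic downstream of ingestion operates on
zonal series, in hectares.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

from .timeutil import is_bimonth_index

__all__ = [
    "WetlandPolygon",
    "Wetlands",
    "RasterSeries",
    "ZonalSeries",
    "StageSeries",
    "BIMONTHLY",
    "DAILY",
]

BIMONTHLY = "bimonthly"
DAILY = "daily"

_ATTR_COLUMNS = ["wetland_type", "type_description", "area_ha", "catchment", "region"]


@dataclasses.dataclass(frozen=True)
class WetlandPolygon:
    """A single typed wetland polygon in a projected (planar) CRS."""

    polygon_id: str
    geometry: shapely.Geometry
    wetland_type: str
    type_description: str = ""
    area_ha: float | None = None  # defaults to geometric area / 1e4 (m^2 -> ha)
    catchment: str = "catchment-1"
    region: str = "south"


class Wetlands:
    """An indexed set of wetland polygons.

    Thin wrapper over a :class:`pandas.DataFrame` (index = polygon_id,
    columns = type/attributes plus a ``geometry`` column of shapely objects),
    validating the invariants the models rely on: unique ids, positive areas,
    valid geometry.
    """

    def __init__(self, frame: pd.DataFrame, crs: str | None = None):
        missing = [c for c in _ATTR_COLUMNS + ["geometry"] if c not in frame.columns]
        if missing:
            raise ValueError(f"wetland frame missing columns: {missing}")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate polygon ids: {dupes}")
        if (frame["area_ha"] <= 0).any():
            bad = frame.index[frame["area_ha"] <= 0].tolist()
            raise ValueError(f"non-positive area_ha for polygons: {bad}")
        invalid = [pid for pid, g in frame["geometry"].items() if not shapely.is_valid(g)]
        if invalid:
            raise ValueError(f"invalid geometries for polygons: {invalid}")
        self.frame = frame
        self.crs = crs

    @classmethod
    def from_polygons(cls, polygons: Iterable[WetlandPolygon], crs: str | None = None) -> "Wetlands":
        rows = []
        for p in polygons:
            area = p.area_ha if p.area_ha is not None else p.geometry.area / 1e4
            rows.append(
                {
                    "polygon_id": p.polygon_id,
                    "wetland_type": p.wetland_type,
                    "type_description": p.type_description,
                    "area_ha": float(area),
                    "catchment": p.catchment,
                    "region": p.region,
                    "geometry": p.geometry,
                }
            )
        frame = pd.DataFrame(rows).set_index("polygon_id")
        return cls(frame, crs=crs)

    @property
    def polygon_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def geometries(self) -> pd.Series:
        return self.frame["geometry"]

    def __len__(self) -> int:
        return len(self.frame)

    def area_ha(self) -> pd.Series:
        return self.frame["area_ha"]

    def type_of(self) -> pd.Series:
        return self.frame["wetland_type"]

    # -- GeoJSON I/O ---------------------------------------------------------

    def to_geojson(self, path: "str | Path") -> None:
        features = []
        for pid, row in self.frame.iterrows():
            props = {k: row[k] for k in _ATTR_COLUMNS}
            features.append(
                {
                    "type": "Feature",
                    "id": pid,
                    "properties": {"polygon_id": pid, **props},
                    "geometry": geom_mapping(row["geometry"]),
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        if self.crs:
            doc["crs_label"] = self.crs
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: "str | Path") -> "Wetlands":
        doc = json.loads(Path(path).read_text())
        polys = []
        for feat in doc["features"]:
            props = feat.get("properties", {})
            pid = str(props.get("polygon_id", feat.get("id")))
            geom = geom_shape(feat["geometry"])
            polys.append(
                WetlandPolygon(
                    polygon_id=pid,
                    geometry=geom,
                    wetland_type=str(props.get("wetland_type", "unknown")),
                    type_description=str(props.get("type_description", "")),
                    area_ha=props.get("area_ha"),
                    catchment=str(props.get("catchment", "catchment-1")),
                    region=str(props.get("region", "south")),
                )
            )
        return cls.from_polygons(polys, crs=doc.get("crs_label"))


@dataclasses.dataclass
class RasterSeries:
    """A gridded environmental time series.

    ``data`` has dims ``(time, y, x)`` with cell-centre coordinates in the
    same planar CRS as the polygons.  ``variable`` is ``depth_mm`` (bimonthly
    maximum inundation depth) or ``moisture_fraction`` (daily root-zone
    relative soil moisture, 0-1).
    """

    data: xr.DataArray
    variable: str
    resolution: str
    cell_size: float  # linear cell size in CRS units (e.g. metres)
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.data.dims != ("time", "y", "x"):
            raise ValueError(f"raster dims must be (time, y, x), got {self.data.dims}")
        t = pd.DatetimeIndex(self.data.coords["time"].values)
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError("raster timestamps must be strictly increasing")
        if self.resolution == DAILY:
            if len(t) > 1 and not (np.diff(t.values).astype("timedelta64[D]") == np.timedelta64(1, "D")).all():
                raise ValueError("daily raster must have consecutive days")
        elif self.resolution == BIMONTHLY:
            if not is_bimonth_index(t):
                raise ValueError("bimonthly raster must use consecutive 2-month block starts")
        else:
            raise ValueError(f"unknown resolution {self.resolution!r}")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.coords["time"].values)

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size * self.cell_size / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) cell-centre coordinates in raster storage order."""
        x = self.data.coords["x"].values
        y = self.data.coords["y"].values
        xx, yy = np.meshgrid(x, y)
        return xx.ravel(), yy.ravel()

    def to_netcdf(self, path: "str | Path") -> None:
        da = self.data.astype("float32")
        ds = da.to_dataset(name=self.variable)
        ds.attrs.update(
            variable=self.variable,
            resolution=self.resolution,
            cell_size=self.cell_size,
            crs=self.crs or "",
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: "str | Path") -> "RasterSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            variable = ds.attrs.get("variable") or list(ds.data_vars)[0]
            da = ds[variable].load()
            return cls(
                data=da,
                variable=variable,
                resolution=ds.attrs["resolution"],
                cell_size=float(ds.attrs["cell_size"]),
                crs=ds.attrs.get("crs") or None,
            )


class _AreaSeries:
    """Shared behaviour of per-polygon area time series (ZonalSeries, StageSeries)."""

    def __init__(self, data: pd.DataFrame, resolution: str):
        if resolution not in (BIMONTHLY, DAILY):
            raise ValueError(f"unknown resolution {resolution!r}")
        data = data.copy()
        data.index = pd.DatetimeIndex(data.index)
        data.columns = data.columns.astype(str)
        self.data = data
        self.resolution = resolution

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def polygon_ids(self) -> pd.Index:
        return self.data.columns

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(future_stack=True).rename("area_ha").reset_index()
        long.columns = ["timestamp", "polygon_id", "area_ha"]
        return long


class ZonalSeries(_AreaSeries):
    """Per-polygon environmental area series: (timestep, polygon) -> area_ha.

    For inundation the value is the polygon area inundated deeper than the
    depth threshold; for soil moisture the area within the moisture band.
    """

    def __init__(self, data: pd.DataFrame, resolution: str, variable: str):
        super().__init__(data, resolution)
        self.variable = variable
        if (self.data.to_numpy() < -1e-9).any():
            raise ValueError("zonal areas must be non-negative")

    def to_csv(self, path: "str | Path") -> None:
        long = self.to_long()
        long.insert(2, "variable", self.variable)
        long.to_csv(path, index=False)

    def to_parquet(self, path: "str | Path") -> None:
        df = self.data.copy()
        df.attrs = {}
        df.to_parquet(path)
        meta = Path(str(path) + ".json")
        meta.write_text(json.dumps({"resolution": self.resolution, "variable": self.variable}))

    @classmethod
    def from_parquet(cls, path: "str | Path") -> "ZonalSeries":
        df = pd.read_parquet(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(df, resolution=meta["resolution"], variable=meta["variable"])

    @classmethod
    def from_csv(cls, path: "str | Path", resolution: str) -> "ZonalSeries":
        long = pd.read_csv(path, parse_dates=["timestamp"])
        variable = str(long["variable"].iloc[0]) if "variable" in long else "unknown"
        wide = long.pivot(index="timestamp", columns="polygon_id", values="area_ha")
        wide.columns = wide.columns.astype(str)
        return cls(wide, resolution=resolution, variable=variable)


class StageSeries(_AreaSeries):
    """Favorable-area series for one model stage.

    ``stage`` is one of adult / regeneration / recruitment / habitat /
    combined.  NaN encodes UNDEFINED (burn-in: incomplete look-back), which
    by construction occupies a contiguous prefix of each series and is never
    coerced to zero.
    """

    STAGES = ("adult", "regeneration", "recruitment", "habitat", "combined")

    def __init__(self, data: pd.DataFrame, resolution: str, stage: str, model: str = "process"):
        super().__init__(data, resolution)
        if stage not in self.STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.stage = stage
        self.model = model

    def defined(self) -> pd.DataFrame:
        return self.data.dropna(how="any")

    def first_defined(self) -> "pd.Timestamp | None":
        d = self.defined()
        return None if d.empty else d.index[0]

    def to_csv(self, path: "str | Path") -> None:
        long = self.to_long()
        long.insert(2, "stage", self.stage)
        long.insert(3, "model", self.model)
        long.to_csv(path, index=False)


def align_check(series: Mapping[str, _AreaSeries]) -> None:
    """Check that several series share one polygon set (order-insensitive)."""
    ids = None
    for name, s in series.items():
        cur = set(s.polygon_ids)
        if ids is None:
            ids = cur
        elif cur != ids:
            raise ValueError(f"{name} covers a different polygon set")
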