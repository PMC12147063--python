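"""Shared fixtures: scenario builds are expensive enough to cache per session."""

import warnings

import numpy as np
import pandas as pd
import pytest
import shapely

from wetfav.core import BIMONTHLY, DAILY, Wetlands, WetlandPolygon, ZonalSeries
from wetfav.synth import scenario_library
from wetfav.timeutil import bimonth_range


@pytest.fixture(scope="session")
def scenarios():
    """All five library scenarios, built once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {name: sc.build() for name, sc in scenario_library().items()}


@pytest.fixture(scope="session")
def textbook(scenarios):
    return scenarios["textbook_recruitment"]


def make_wetlands(n=3, cells=10, cell_size=100.0, types=None, catchments=None, regions=None):
    """Row of square polygons of ``cells`` x ``cells`` grid cells each."""
    polys = []
    for i in range(n):
        polys.append(
            WetlandPolygon(
                polygon_id=f"p{i}",
                geometry=shapely.box(i * cells * cell_size, 0, (i + 1) * cells * cell_size, cells * cell_size),
                wetland_type=(types or ["type-a"] * n)[i],
                type_description=(types or ["type-a"] * n)[i],
                catchment=(catchments or ["c0"] * n)[i],
                region=(regions or ["south"] * n)[i],
            )
        )
    return Wetlands.from_polygons(polys, crs="synthetic-planar")


def make_bimonthly(values, start="1990-01-01", columns=("p0",)):
    """Bimonthly ZonalSeries from a (T,) or (T, P) array."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and len(columns) == 1:
        arr = arr.T
    idx = bimonth_range(start, arr.shape[0])
    return ZonalSeries(pd.DataFrame(arr, index=idx, columns=list(columns)),
                       BIMONTHLY, "inundated_area")


def make_daily(values, start="1990-01-01", columns=("p0",)):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and len(columns) == 1:
        arr = arr.T
    idx = pd.date_range(start, periods=arr.shape[0])
    return ZonalSeries(pd.DataFrame(arr, index=idx, columns=list(columns)),
                       DAILY, "moist_area")
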