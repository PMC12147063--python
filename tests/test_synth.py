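"""Generator guarantees: determinism, exact nesting, engineered truths."""

import numpy as np
import pandas as pd
import pytest

from wetfav.core import Wetlands
from wetfav.process import sustained_moisture_area
from wetfav.synth import (
    FloodEvent,
    MoistureModel,
    ScenarioSpec,
    exact_inundation_zonal,
    exact_moisture_zonal,
    gen_inundation,
    gen_landscape,
    gen_soil_moisture,
    scenario_library,
)
from wetfav.zonal import inundated_area_series, moist_area_series


def small_spec(**kw):
    base = dict(
        seed=5,
        n_polygons=4,
        poly_shape=(6, 6),
        years=3,
        start="1996-07-01",
        events=(FloodEvent(start_step=2, peak_frac=0.5, recession_steps=2),),
        moisture=MoistureModel(band_days=40.0),
    )
    base.update(kw)
    return ScenarioSpec(**base)


class TestLandscape:
    def test_single_polygon(self):
        land = gen_landscape(small_spec(n_polygons=1))
        assert len(land.wetlands) == 1
        assert land.n_cells("w000") == 36

    def test_seed_determinism(self):
        a, b = gen_landscape(small_spec()), gen_landscape(small_spec())
        assert a.wetlands.frame.drop(columns="geometry").equals(
            b.wetlands.frame.drop(columns="geometry")
        )
        for pid in a.cell_order:
            assert np.array_equal(a.cell_order[pid], b.cell_order[pid])
        ra, rb = gen_inundation(a), gen_inundation(b)
        assert np.array_equal(ra.data.values, rb.data.values)
        ma, mb = gen_soil_moisture(a), gen_soil_moisture(b)
        assert np.array_equal(ma.data.values, mb.data.values)

    def test_bathymetry_rank_is_strict_total_order(self):
        land = gen_landscape(small_spec())
        for pid, order in land.cell_order.items():
            assert len(set(order)) == land.n_cells(pid)

    def test_type_shares_follow_palette_weights(self):
        palette = (("A", "a", 0.6), ("B", "b", 0.3), ("C", "c", 0.1))
        land = gen_landscape(small_spec(n_polygons=500, poly_shape=(2, 2), type_palette=palette))
        shares = land.wetlands.frame["wetland_type"].value_counts(normalize=True)
        # multinomial sampling error at n=500: ~3 sigma
        for t, p in [("A", 0.6), ("B", 0.3), ("C", 0.1)]:
            assert abs(shares.get(t, 0.0) - p) < 3 * np.sqrt(p * (1 - p) / 500)


class TestNesting:
    def test_wet_sets_are_bathymetry_prefixes(self):
        land = gen_landscape(small_spec())
        raster = gen_inundation(land)
        counts = land.wet_counts()
        vals = raster.data.values.reshape(len(land.steps), -1)
        for pid, order in land.cell_order.items():
            for t in range(len(land.steps)):
                wet = set(np.nonzero(vals[t] > 5.0)[0]) & set(order)
                k = counts[pid].iloc[t]
                assert wet == set(order[:k])

    def test_consecutive_steps_subset_ordered(self):
        land = gen_landscape(small_spec())
        raster = gen_inundation(land)
        vals = raster.data.values.reshape(len(land.steps), -1) > 5.0
        for pid, order in land.cell_order.items():
            sub = vals[:, order]
            for t in range(len(land.steps) - 1):
                a, b = set(np.nonzero(sub[t])[0]), set(np.nonzero(sub[t + 1])[0])
                assert a <= b or b <= a

    def test_in_band_sets_are_prefixes(self):
        land = gen_landscape(small_spec())
        raster = gen_soil_moisture(land)
        m = raster.data.values.reshape(len(land.days), -1)
        in_band = (m >= 0.10) & (m <= 0.30)
        for pid, order in land.cell_order.items():
            sub = in_band[:, order]
            counts = sub.sum(axis=1)
            # prefix property: the first `count` ranks are exactly the in-band set
            for t in np.nonzero(counts)[0]:
                assert sub[t, : counts[t]].all() and not sub[t, counts[t]:].any()


class TestExactZonal:
    def test_matches_geometry_path_inundation(self):
        land = gen_landscape(small_spec())
        got = inundated_area_series(gen_inundation(land), land.wetlands).data
        want = exact_inundation_zonal(land).data
        assert np.array_equal(got.to_numpy(), want[got.columns].to_numpy())

    def test_matches_geometry_path_moisture(self):
        land = gen_landscape(small_spec())
        got = moist_area_series(gen_soil_moisture(land), land.wetlands).data
        want = exact_moisture_zonal(land).data
        assert np.array_equal(got.to_numpy(), want[got.columns].to_numpy())


class TestMoistureModel:
    def test_in_band_duration_follows_decay_closed_form(self):
        mm = MoistureModel(band_days=40.0, entry_days=3, noise_sd=0.0)
        prof = mm.profile(200)
        in_band = (prof >= 0.10) & (prof <= 0.30)
        first, last = np.nonzero(in_band)[0][[0, -1]]
        assert first == mm.entry_days
        assert last == pytest.approx(mm.entry_days + mm.band_days, abs=1)

    def test_designed_sustained_window(self):
        # single flood: 14 consecutive in-band days exist at the designed day
        land = gen_landscape(small_spec(moisture=MoistureModel(band_days=40.0, noise_sd=0.0)))
        zs = exact_moisture_zonal(land)
        ev = land.spec.events_for("w000")[0]
        c0 = land.clock_start_day(ev)
        d = land.days[c0 + land.spec.moisture.entry_days + 13]
        assert sustained_moisture_area(zs, "w000", d, 14) > 0

    def test_never_flooded_dry_cell_never_in_band(self):
        spec = small_spec(events=(), moisture=MoistureModel(noise_sd=0.0))
        land = gen_landscape(spec)
        m = gen_soil_moisture(land).data.values
        assert (m < 0.10).all()

    def test_noise_never_reaches_the_band(self):
        land = gen_landscape(small_spec(moisture=MoistureModel(noise_sd=0.05)))
        m = gen_soil_moisture(land).data.values.reshape(len(land.days), -1)
        never_flooded = np.ones(m.shape[1], dtype=bool)
        for pid, order in land.cell_order.items():
            k = int(round(0.5 * land.n_cells(pid)))
            never_flooded[order[:k]] = False
        assert (m[:, never_flooded] < 0.10).all()

    def test_overlapping_drying_windows_rejected(self):
        spec = small_spec(
            events=(
                FloodEvent(start_step=2, peak_frac=0.5),
                FloodEvent(start_step=3, peak_frac=0.5),
            )
        )
        land = gen_landscape(spec)
        with pytest.raises(ValueError, match="overlapping drying windows"):
            gen_soil_moisture(land)

    def test_decoupled_event_is_invisible_to_moisture(self):
        coupled = small_spec()
        extra = small_spec(
            events=(
                FloodEvent(start_step=2, peak_frac=0.5, recession_steps=2),
                FloodEvent(start_step=6, peak_frac=0.8, moisture_coupled=False),
            )
        )
        a = gen_soil_moisture(gen_landscape(coupled))
        b = gen_soil_moisture(gen_landscape(extra))
        assert np.array_equal(a.data.values, b.data.values)


class TestScenarioLibrary:
    def test_library_names(self):
        lib = scenario_library()
        assert set(lib) == {
            "textbook_recruitment",
            "drowned_seedlings",
            "senescent_stand",
            "expansion_front",
            "adult_drowning",
        }

    def test_fixture_reproducibility(self, scenarios):
        again = scenario_library()["textbook_recruitment"].build()
        fx = scenarios["textbook_recruitment"]
        assert fx.inundation.data.equals(again.inundation.data)
        assert fx.moisture.data.equals(again.moisture.data)


def test_write_fixture_roundtrip(tmp_path, scenarios):
    from wetfav.core import RasterSeries
    from wetfav.synth import write_fixture

    fx = scenarios["textbook_recruitment"]
    write_fixture(fx, tmp_path)
    w = Wetlands.from_geojson(tmp_path / "polygons.geojson")
    assert len(w) == len(fx.landscape.wetlands)
    r = RasterSeries.from_netcdf(tmp_path / "inundation.nc")
    assert np.allclose(r.data.values, fx.inundation_raster.data.values)
    assert (tmp_path / "manifest.json").exists()
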