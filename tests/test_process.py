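"""Life-cycle engine: rounding rules, window arithmetic, stage conditioning."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from wetfav.core import BIMONTHLY
from wetfav.process import (
    adult_favorability,
    conditional_min,
    continuous_inundation_area,
    excess_run_steps,
    months_to_steps,
    recruitment_favorability,
    regeneration_favorability,
    run_process_model,
    sustained_moisture_area,
)
from wetfav.requirements import SPECIES_REQUIREMENTS, SpeciesRequirements
from wetfav.timeutil import Season, bimonth_index_of

from conftest import make_bimonthly, make_daily, make_wetlands


@pytest.mark.parametrize(
    "months, steps",
    [(4.5, 3), (2, 1), (48, 24), (0.5, 1), (6, 3), (3, 2)],
)
def test_months_to_steps_rounds_up(months, steps):
    assert months_to_steps(months) == steps


@pytest.mark.parametrize(
    "months, steps",
    [(5, 3), (1, 1), (24, 13), (2, 2), (12, 7), (96, 49)],
)
def test_excess_run_steps_smallest_lethal_run(months, steps):
    # smallest n with 2n > months, since in-step inundation counts as continuous
    assert excess_run_steps(months) == steps


@pytest.mark.parametrize("fn", [months_to_steps, excess_run_steps])
def test_nonpositive_durations_rejected(fn):
    with pytest.raises(ValueError):
        fn(0)
    with pytest.raises(ValueError):
        fn(-3)


def test_conditional_min_rule():
    assert conditional_min(0.0, 50.0) == 0.0
    assert conditional_min(50.0, 50.0) == 50.0
    assert conditional_min(12.5, 30.0) == 12.5
    assert np.isnan(conditional_min(np.nan, 30.0))


class TestRunWindows:
    def test_continuous_inundation_minimum_over_run(self):
        z = make_bimonthly([80.0, 35.0, 60.0])
        assert continuous_inundation_area(z, "p0", 2, 3) == 35.0

    def test_broken_run_is_zero(self):
        z = make_bimonthly([80.0, 0.0, 60.0])
        assert continuous_inundation_area(z, "p0", 2, 3) == 0.0

    def test_constant_run(self):
        z = make_bimonthly([40.0, 40.0, 40.0])
        assert continuous_inundation_area(z, "p0", z.times[-1], 3) == 40.0

    def test_insufficient_history_undefined(self):
        z = make_bimonthly([80.0, 35.0, 60.0])
        assert np.isnan(continuous_inundation_area(z, "p0", 1, 3))

    def test_sustained_moisture_sawtooth_minimum(self):
        vals = [10.0, 4.0, 8.0, 12.0, 4.0, 9.0, 11.0]
        z = make_daily(vals)
        assert sustained_moisture_area(z, "p0", 6, 5) == 4.0
        assert np.isnan(sustained_moisture_area(z, "p0", 2, 5))

    def test_one_dry_day_breaks_the_run(self):
        z = make_daily([15.0] * 6 + [0.0] + [15.0] * 7)
        assert sustained_moisture_area(z, "p0", 13, 14) == 0.0
        assert sustained_moisture_area(z, "p0", 13, 7) == 15.0


def _redgum_like(**overrides):
    base = SPECIES_REQUIREMENTS["red_gum"]
    return dataclasses.replace(base, **overrides)


class TestAdult:
    def test_single_flood_window_trace(self):
        # one in-season flood; 48-month interval = 24 steps: favorable for
        # exactly 24 steps starting at the flood, zero afterwards
        vals = np.zeros(60)
        t0 = 27  # Jul-Aug 1994 for a 1990-01 start: inside the Jul-Dec season
        vals[t0] = 100.0
        z = make_bimonthly(vals, start="1990-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        fav = adult_favorability(z, _redgum_like(adult_excess_inundation_months=None), w)
        col = fav.data["p0"]
        assert col.iloc[:24].isna().all()  # burn-in
        assert (col.iloc[t0 : t0 + 24] == 100.0).all()
        assert (col.iloc[t0 + 24 :] == 0.0).all()

    def test_out_of_season_flood_does_not_count(self):
        vals = np.zeros(60)
        vals[26] = 100.0  # May-Jun 1994: outside Jul-Dec adult season
        z = make_bimonthly(vals, start="1990-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        fav = adult_favorability(z, _redgum_like(adult_excess_inundation_months=None), w)
        assert (fav.data["p0"].dropna() == 0.0).all()

    def test_continuous_inundation_zeroes_favorability(self):
        vals = np.full(60, 100.0)
        z = make_bimonthly(vals, start="1990-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        fav = adult_favorability(z, SPECIES_REQUIREMENTS["red_gum"], w)
        assert (fav.data["p0"].dropna() == 0.0).all()

    def test_no_inundation_is_zero_after_burn_in(self):
        z = make_bimonthly(np.zeros(30), start="1990-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        fav = adult_favorability(z, _redgum_like(adult_excess_inundation_months=None), w)
        assert fav.data["p0"].iloc[:24].isna().all()
        assert (fav.data["p0"].iloc[24:] == 0.0).all()

    def test_burn_in_length_is_interval_steps(self):
        z = make_bimonthly(np.zeros(130 * 2), start="1988-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        fav = adult_favorability(z, SPECIES_REQUIREMENTS["coolabah"], w)
        assert fav.first_defined() == pd.Timestamp("2008-01-01")


class TestStageChain:
    """Hand-traced designed scenario on explicit zonal series."""

    @staticmethod
    def _series(adult_flood=60.0, moist_level=25.0, start="2000-07-01"):
        # inundation: flood at step 25 (Sep-Oct 2004, in-season)
        steps = np.zeros(42)
        steps[25] = adult_flood
        inund = make_bimonthly(steps, start=start)
        # moisture: in-band area from 2004-09-21 for 160 days
        days = pd.date_range(start, periods=42 * 61)[: (pd.Timestamp("2007-06-30") - pd.Timestamp(start)).days + 1]
        m = np.zeros(len(days))
        i0 = (pd.Timestamp("2004-09-21") - pd.Timestamp(start)).days
        m[i0 : i0 + 160] = moist_level
        moist = make_daily(m, start=start)
        return inund, moist

    def test_regeneration_is_min_of_adult_moisture_flood(self):
        inund, moist = self._series()
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        reqs = _redgum_like()
        stages = run_process_model(inund, moist, reqs, w)
        regen = stages["regeneration"].data["p0"]
        # day in season whose 14-day moist window starts inside the flood step
        d = pd.Timestamp("2004-10-20")
        assert regen.loc[d] == 25.0  # min(adult 60, moisture 25, flood 60)
        assert stages["adult"].data["p0"].loc["2004-09-01"] == 60.0

    def test_out_of_season_day_is_zero(self):
        inund, moist = self._series()
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        stages = run_process_model(inund, moist, _redgum_like(), w)
        regen = stages["regeneration"].data["p0"]
        assert regen.loc["2005-01-05"] == 0.0  # January: outside Sep-Dec

    def test_zero_adult_zeroes_regeneration(self):
        inund, moist = self._series()
        # remove the flood from the adult look-back by moving it out of season
        vals = inund.data["p0"].to_numpy().copy()
        vals[25] = 0.0
        vals[26] = 60.0  # Nov-Dec is in red gum season; use May-Jun instead
        vals[26] = 0.0
        vals[29] = 60.0  # May-Jun 2005: out of adult season AND regen season
        inund2 = make_bimonthly(vals, start="2000-07-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        stages = run_process_model(inund2, moist, _redgum_like(), w)
        assert (stages["regeneration"].data["p0"].dropna() == 0.0).all()

    def test_recruitment_hand_trace(self):
        # regeneration 25 ha at d0; moisture stays at 18 ha over the seedling
        # period; a single isolated inundated step cannot form the 2-step
        # lethal run, so recruitment = min(25, 18) = 18
        inund, moist = self._series()
        m = moist.data["p0"].to_numpy().copy()
        days = moist.times
        i0 = (pd.Timestamp("2004-09-21") - days[0]).days
        m[i0 : i0 + 320] = 25.0
        d0 = pd.Timestamp("2004-10-20")
        j = (d0 - days[0]).days
        m[j + 1 : j + 320] = 18.0  # drops to 18 after the regeneration day
        moist2 = make_daily(m, start=str(days[0].date()))
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        stages = run_process_model(inund, moist2, _redgum_like(), w)
        # the day whose 4.5-month look-back lands exactly on d0
        d = pd.Timestamp("2005-03-04")  # - 4 months - 15 days = 2004-10-20
        assert stages["regeneration"].data["p0"].loc[d0] == 25.0
        assert stages["recruitment"].data["p0"].loc[d] == 18.0

    def test_lignum_dies_with_any_inundated_step_in_window(self):
        # same geometry but lignum: excess run of 1 step; the germination
        # step itself is inundated, so recruitment is zero
        inund, moist = self._series()
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        reqs = SPECIES_REQUIREMENTS["lignum"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stages = run_process_model(inund, moist, reqs, w)
        rec = stages["recruitment"].data["p0"].dropna()
        assert (rec == 0.0).all()

    def test_all_dry_inputs_are_zero_after_burn_in(self):
        inund = make_bimonthly(np.zeros(42), start="2000-07-01")
        moist = make_daily(np.zeros(42 * 61 - 200), start="2000-07-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        stages = run_process_model(inund, moist, _redgum_like(), w)
        for s in stages.values():
            defined = s.defined()
            assert (defined.to_numpy() == 0.0).all()
            assert len(defined)


class TestInvariants:
    def test_stage_ordering_under_conditioning_offsets(self, textbook):
        from wetfav.requirements import SPECIES_REQUIREMENTS
        from wetfav.timeutil import shift_months

        reqs = SPECIES_REQUIREMENTS["red_gum"]
        w = textbook.landscape.wetlands
        st = run_process_model(textbook.inundation, textbook.moisture, reqs, w)
        adult, regen, rec = (st[k] for k in ("adult", "regeneration", "recruitment"))
        # regeneration(d) <= adult(step containing d - D + 1)
        D = reqs.regeneration_moisture_days
        s0 = bimonth_index_of(regen.times - pd.Timedelta(days=D - 1), adult.times[0])
        ok = (s0 >= 0) & regen.data.notna().all(axis=1).to_numpy()
        a_at = adult.data.to_numpy()[s0[ok]]
        assert (regen.data.to_numpy()[ok] <= a_at + 1e-9).all()
        # recruitment(d) <= regeneration(d0)
        d0 = shift_months(rec.times, -reqs.seedling_moisture_months)
        i0 = (d0 - regen.times[0]).days.to_numpy()
        ok = (i0 >= 0) & rec.data.notna().all(axis=1).to_numpy()
        r_at = regen.data.to_numpy()[i0[ok]]
        assert (rec.data.to_numpy()[ok] <= r_at + 1e-9).all()

    def test_bounds_and_burn_in_prefix(self, textbook):
        reqs = SPECIES_REQUIREMENTS["red_gum"]
        w = textbook.landscape.wetlands
        areas = w.area_ha()
        st = run_process_model(textbook.inundation, textbook.moisture, reqs, w)
        for s in st.values():
            for pid in s.polygon_ids:
                col = s.data[pid]
                vals = col.dropna()
                assert ((vals >= 0) & (vals <= areas[pid] + 1e-9)).all()
                # NaN only in a contiguous prefix
                na = col.isna().to_numpy()
                assert not (np.diff(na.astype(int)) > 0).any()

    def test_disabled_stricture_equals_huge_threshold(self, textbook):
        w = textbook.landscape.wetlands
        base = SPECIES_REQUIREMENTS["red_gum"]
        off = dataclasses.replace(
            base, adult_excess_inundation_months=None, seedling_excess_inundation_months=None
        )
        # large enough that no lethal run fits the data, small enough that the
        # look-back still fits inside the series
        huge = dataclasses.replace(
            base,
            adult_excess_inundation_months=40.0,
            seedling_excess_inundation_months=40.0,
        )
        st_off = run_process_model(textbook.inundation, textbook.moisture, off, w)
        st_huge = run_process_model(textbook.inundation, textbook.moisture, huge, w)
        for k in st_off:
            a, b = st_off[k].data, st_huge[k].data
            common = a.dropna().index.intersection(b.dropna().index)
            assert len(common) > 0
            assert np.allclose(a.loc[common], b.loc[common])

    def test_short_series_warns_and_is_all_undefined(self):
        z = make_bimonthly(np.zeros(6), start="1990-01-01")
        w = make_wetlands(n=1, cells=10)
        w.frame.index = pd.Index(["p0"], name="polygon_id")
        with pytest.warns(UserWarning, match="burn-in"):
            fav = adult_favorability(z, SPECIES_REQUIREMENTS["red_gum"], w)
        assert fav.data.isna().all().all()


def test_regional_season_resolution():
    reqs = SPECIES_REQUIREMENTS["black_box"]
    north = reqs.resolve_season("regeneration_season", "north")
    south = reqs.resolve_season("regeneration_season", "south")
    assert north == Season(5, 10)
    assert south == Season(11, 3)
    with pytest.raises(KeyError, match="region"):
        reqs.resolve_season("regeneration_season", "west")
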