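"""Buffer aggregation, window averaging and control-median count scores."""

import numpy as np
import pandas as pd
import pytest

from pestewas.exposure import (
    annual_buffer_exposure,
    average_window,
    dichotomize_and_count,
)


def apps_df(rows):
    return pd.DataFrame(rows, columns=["chemical_code", "year", "pounds", "acres", "x", "y"])


def addr_df(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "x", "y", "start_year", "end_year", "kind"]
    )


class TestAnnualBufferExposure:
    def test_only_in_buffer_events_count(self):
        # 10 lbs / 2 acres at 300 m is inside; 5 lbs / 1 acre at 600 m is not
        apps = apps_df([(1001, 2000, 10.0, 2.0, 300.0, 0.0),
                        (1001, 2000, 5.0, 1.0, 600.0, 0.0)])
        addr = addr_df([("P1", 0.0, 0.0, 1990, 2005, "residential")])
        out = annual_buffer_exposure(apps, addr, radius_m=500.0)
        assert len(out) == 1
        assert out.iloc[0]["exposure"] == pytest.approx(5.0)

    def test_boundary_is_inclusive(self):
        apps = apps_df([(1001, 2000, 8.0, 2.0, 500.0, 0.0)])
        addr = addr_df([("P1", 0.0, 0.0, 2000, 2000, "residential")])
        out = annual_buffer_exposure(apps, addr, radius_m=500.0)
        assert out.iloc[0]["exposure"] == pytest.approx(4.0)

    def test_residential_and_workplace_buffers_add(self):
        apps = apps_df([(1001, 2000, 6.0, 2.0, 0.0, 0.0),
                        (1001, 2000, 4.0, 1.0, 5000.0, 0.0)])
        addr = addr_df([("P1", 0.0, 0.0, 1990, 2005, "residential"),
                        ("P1", 5000.0, 0.0, 1999, 2001, "workplace")])
        out = annual_buffer_exposure(apps, addr)
        assert out.iloc[0]["exposure"] == pytest.approx(3.0 + 4.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        apps = apps_df([
            (int(rng.choice([1001, 1002, 2001])), int(rng.integers(1990, 2010)),
             float(rng.lognormal(2, 1)), float(rng.lognormal(0.5, 0.5)),
             float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000)))
            for _ in range(200)
        ])
        addr = addr_df([
            (f"P{i}", float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000)),
             1990, int(rng.integers(1995, 2010)),
             "residential" if j == 0 else "workplace")
            for i in range(5) for j in range(rng.integers(1, 3))
        ])
        out = annual_buffer_exposure(apps, addr, radius_m=500.0)
        got = {(r.participant_id, r.chemical_code, r.year): r.exposure
               for r in out.itertuples()}

        expect: dict = {}
        for ad in addr.itertuples():
            for ap in apps.itertuples():
                d2 = (ap.x - ad.x) ** 2 + (ap.y - ad.y) ** 2
                if d2 <= 500.0**2 and ad.start_year <= ap.year <= ad.end_year:
                    key = (ad.participant_id, ap.chemical_code, ap.year)
                    expect[key] = expect.get(key, 0.0) + ap.pounds / ap.acres
        assert set(got) == set(expect)
        for key in expect:
            assert got[key] == pytest.approx(expect[key], rel=1e-12)

    def test_permutation_of_inputs_is_irrelevant(self):
        rng = np.random.default_rng(3)
        apps = apps_df([
            (1001, 2000, float(rng.lognormal(2, 1)), 1.0,
             float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
            for _ in range(50)
        ])
        addr = addr_df([("P1", 200.0, 200.0, 1999, 2001, "residential"),
                        ("P1", 800.0, 800.0, 2000, 2000, "workplace")])
        a = annual_buffer_exposure(apps, addr)
        b = annual_buffer_exposure(
            apps.sample(frac=1, random_state=1), addr.iloc[::-1]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_participant_without_addresses_is_excluded_with_warning(self, caplog):
        apps = apps_df([(1001, 2000, 1.0, 1.0, 0.0, 0.0)])
        addr = addr_df([("P1", 0.0, 0.0, 2000, 2000, "residential")])
        with caplog.at_level("WARNING"):
            out = annual_buffer_exposure(apps, addr, participants=["P1", "P2"])
        assert "P2" in caplog.text
        assert set(out["participant_id"]) == {"P1"}


class TestAverageWindow:
    def test_zero_years_count_in_denominator(self):
        annual = pd.DataFrame(
            {"participant_id": ["P1"], "chemical_code": [1001],
             "year": [1974], "exposure": [2.0]}
        )
        prof = average_window(annual, {"P1": 1975}, chemicals=[1001])
        assert prof.loc["P1", 1001] == pytest.approx(1.0)

    def test_all_zero_years_give_zero(self):
        annual = pd.DataFrame(columns=["participant_id", "chemical_code", "year", "exposure"])
        prof = average_window(annual, {"P1": 2000}, chemicals=[1001, 1002])
        assert (prof.to_numpy() == 0).all()

    def test_matches_hand_computed_means(self):
        annual = pd.DataFrame(
            {
                "participant_id": ["P1", "P1", "P1", "P2"],
                "chemical_code": [1001, 1001, 1002, 1001],
                "year": [1980, 1990, 1985, 1974],
                "exposure": [3.0, 7.0, 5.0, 2.0],
            }
        )
        prof = average_window(annual, {"P1": 1993, "P2": 1983}, chemicals=[1001, 1002])
        assert prof.loc["P1", 1001] == pytest.approx(10.0 / 20)   # 1974..1993
        assert prof.loc["P1", 1002] == pytest.approx(5.0 / 20)
        assert prof.loc["P2", 1001] == pytest.approx(2.0 / 10)    # 1974..1983

    def test_years_after_blood_draw_are_ignored(self):
        annual = pd.DataFrame(
            {"participant_id": ["P1", "P1"], "chemical_code": [1001, 1001],
             "year": [1980, 1990], "exposure": [4.0, 100.0]}
        )
        prof = average_window(annual, {"P1": 1983}, chemicals=[1001])
        assert prof.loc["P1", 1001] == pytest.approx(4.0 / 10)

    def test_draw_year_before_window_start_rejected(self):
        annual = pd.DataFrame(columns=["participant_id", "chemical_code", "year", "exposure"])
        with pytest.raises(ValueError, match="1974"):
            average_window(annual, {"P1": 1970}, chemicals=[1001])


class TestDichotomizeAndCount:
    def _profiles(self, values, chems):
        return pd.DataFrame(values, columns=chems)

    def test_strict_inequality_at_the_control_median(self):
        chems = [1001]
        prof = pd.DataFrame(
            {1001: [0.0, 0.0, 1.0, 2.0, 3.0, 2.0, 1.0]},
            index=[f"C{i}" for i in range(5)] + ["P_above", "P_at"],
        )
        res = dichotomize_and_count(prof, [f"C{i}" for i in range(5)], chems, [])
        assert res.thresholds[1001] == pytest.approx(1.0)
        assert res.indicators.loc["P_above", 1001] == 1
        assert res.indicators.loc["P_at", 1001] == 0

    def test_full_copper_exposure_reaches_count_15(self):
        chems = list(range(1001, 1016))
        rows = {c: [0.0, 0.0, 0.1, 0.2, 5.0] for c in chems}
        prof = pd.DataFrame(rows, index=["C1", "C2", "C3", "C4", "P1"])
        res = dichotomize_and_count(prof, ["C1", "C2", "C3", "C4"], chems, [])
        assert res.counts.loc["P1", "copper_count"] == 15

    def test_counts_equal_brute_force_indicators(self):
        rng = np.random.default_rng(8)
        chems = [1001, 1002, 2001, 2002, 2003]
        prof = pd.DataFrame(
            rng.exponential(1.0, size=(30, 5)) * (rng.random((30, 5)) < 0.6),
            index=[f"P{i}" for i in range(30)], columns=chems,
        )
        controls = [f"P{i}" for i in range(10)]
        res = dichotomize_and_count(prof, controls, [1001, 1002], [2001, 2002, 2003])
        for pid in prof.index:
            cu = sum(
                prof.loc[pid, c] > np.median(prof.loc[controls, c]) for c in [1001, 1002]
            )
            op = sum(
                prof.loc[pid, c] > np.median(prof.loc[controls, c])
                for c in [2001, 2002, 2003]
            )
            assert res.counts.loc[pid, "copper_count"] == cu
            assert res.counts.loc[pid, "op_count"] == op

    def test_increasing_one_exposure_never_lowers_the_count(self):
        rng = np.random.default_rng(9)
        chems = [1001, 1002, 1003]
        prof = pd.DataFrame(rng.exponential(1, (20, 3)),
                            index=[f"P{i}" for i in range(20)], columns=chems)
        controls = [f"P{i}" for i in range(8)]
        base = dichotomize_and_count(prof, controls, chems, [])
        bumped = prof.copy()
        bumped.loc["P15", 1002] += 10.0
        res = dichotomize_and_count(bumped, controls, chems, [])
        assert (
            res.counts.loc["P15", "copper_count"]
            >= base.counts.loc["P15", "copper_count"]
        )

    def test_at_most_half_of_controls_exceed_their_own_median(self):
        rng = np.random.default_rng(10)
        chems = [1001, 1002, 1003, 1004]
        prof = pd.DataFrame(rng.lognormal(0, 1, (41, 4)),
                            index=[f"P{i}" for i in range(41)], columns=chems)
        controls = [f"P{i}" for i in range(21)]
        res = dichotomize_and_count(prof, controls, chems, [])
        frac = res.indicators.loc[controls].mean(axis=0)
        assert (frac <= 0.5 + 1e-12).all()

    def test_empty_controls_rejected(self):
        prof = pd.DataFrame({1001: [1.0]}, index=["P1"])
        with pytest.raises(ValueError, match="non-empty"):
            dichotomize_and_count(prof, [], [1001], [])
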