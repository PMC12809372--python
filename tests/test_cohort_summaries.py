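"""Attrition accounting, percentage rounding, the long-stay comparator, and
drug point prevalence."""

import numpy as np
import pandas as pd
import pytest

import nhobs
from nhobs.cohort_summaries import long_stay_days

from tests.oracles import build_flagged_days, small_params


def day_grid(n_days, rid="A", eid="E1", start="2016-01-01",
             enrolled=1, snf_days=(), hosp_days=()):
    """n_days consecutive flagged days; snf/hosp_days are 1-based day indices."""
    dates = pd.date_range(start, periods=n_days)
    return pd.DataFrame({
        "resident_id": rid, "episode_id": eid, "date": dates,
        "day_index": np.arange(1, n_days + 1),
        "enrolled": enrolled,
        "snf": [1 if i in snf_days else 0 for i in range(1, n_days + 1)],
        "hospital": [1 if i in hosp_days else 0 for i in range(1, n_days + 1)],
    })


class TestPercent:
    @pytest.mark.parametrize("num,den,expected", [
        (724, 1000, 72.4),
        (3961, 10000, 39.6),
        (1, 3, 33.3),
        (0, 100, 0.0),
        (15, 10000, 0.2),   # 0.15% rounds half away from zero
        (25, 1000, 2.5),
    ])
    def test_one_decimal_half_away_from_zero(self, num, den, expected):
        assert nhobs.percent(num, den) == expected

    def test_zero_denominator_reports_absent(self):
        assert nhobs.percent(5, 0) is None


class TestAttrition:
    def test_figure1_fixture_matches_the_hand_audit(self, figure1):
        _, days = build_flagged_days(figure1)
        expect = nhobs.FIXTURE_EXPECTATIONS["figure1_schematic"]
        att = nhobs.summarize_attrition(days)
        allrow = att.loc["all"]
        assert allrow["total_days"] == expect["nh_days"]
        assert allrow["snf_days"] == expect["snf_days"]
        assert allrow["hospital_days"] == expect["hospital_days"]
        assert allrow["observable_days"] == expect["observable_days"]
        assert allrow["n_observable_episodes"] == \
            len(expect["observable_episode_lengths"])
        # per-bin hand counts: SNF removes days 1-20, hospital days 71-75
        assert list(att.loc[["1–30", "31–60", "61–100", "101+"],
                            "observable_days"]) == [10, 30, 35, 22]

    def test_fully_favorable_grid_is_100pct_observable(self):
        att = nhobs.summarize_attrition(day_grid(50))
        assert att.loc["all", "pct_observable_of_enrolled"] == 100.0
        assert att.loc["all", "pct_observable_of_total"] == 100.0

    def test_partition_and_ordering_identities_hold(self, small_cohort):
        _, days = build_flagged_days(small_cohort)
        att = nhobs.summarize_attrition(days)
        for _, row in att.iterrows():
            assert row["unenrolled_days"] + row["enrolled_days"] == row["total_days"]
            assert row["snf_days"] + row["enrolled_not_snf_days"] == row["enrolled_days"]
            assert (row["hospital_days"] + row["enrolled_not_hospital_days"]
                    == row["enrolled_days"])
            assert row["observable_days"] <= row["enrolled_days"] <= row["total_days"]
            # SNF + hospital can double-count a day, never undercount
            assert (row["snf_days"] + row["hospital_days"]
                    >= row["enrolled_days"] - row["observable_days"])
        bins = att.drop(index="all")
        for col in ("total_days", "unenrolled_days", "enrolled_days",
                    "observable_days"):
            assert bins[col].sum() == att.loc["all", col]

    def test_multi_reason_days_increment_both_reason_counters(self):
        g = day_grid(10, snf_days=range(1, 6), hosp_days=range(4, 9))
        att = nhobs.summarize_attrition(g)
        assert att.loc["all", "snf_days"] == 5
        assert att.loc["all", "hospital_days"] == 5
        # unique removals: days 1-8
        assert att.loc["all", "observable_days"] == 2

    def test_empty_grid_reports_zero_counts_and_absent_percentages(self):
        att = nhobs.summarize_attrition(day_grid(0).iloc[0:0])
        assert att["total_days"].eq(0).all()
        assert att["pct_observable_of_enrolled"].isna().all()

    def test_attrition_percentages_recompute_from_counts(self):
        att = nhobs.summarize_attrition(day_grid(100, snf_days=range(1, 21)))
        att2 = nhobs.attrition_percentages(
            att.drop(columns=["pct_observable_of_enrolled",
                              "pct_observable_of_total"]))
        assert att2.loc["all", "pct_observable_of_enrolled"] == 80.0


class TestLongStayMethod2:
    def test_episode_reaching_cutoff_qualifies_with_days_from_cutoff(self):
        g = day_grid(150)
        cls = nhobs.classify_long_stay_method2(g)
        assert cls.iloc[0]["long_stay"] == 1
        assert cls.iloc[0]["qualifying_date"] == pd.Timestamp("2016-01-01") \
            + pd.Timedelta(days=100)
        assert len(long_stay_days(g, cls)) == 50

    def test_100_day_episode_is_short_stay(self):
        cls = nhobs.classify_long_stay_method2(day_grid(100))
        assert cls.iloc[0]["long_stay"] == 0
        assert pd.isna(cls.iloc[0]["qualifying_date"])

    def test_101_day_episode_contributes_one_long_stay_day(self):
        g = day_grid(101)
        cls = nhobs.classify_long_stay_method2(g)
        assert cls.iloc[0]["long_stay"] == 1
        assert len(long_stay_days(g, cls)) == 1
        assert len(long_stay_days(g, cls, attribution="whole_episode")) == 101

    def test_cutoff_one_returns_every_episode(self, small_cohort):
        _, days = build_flagged_days(small_cohort)
        cls = nhobs.classify_long_stay_method2(days, cutoff=1)
        assert (cls["long_stay"] == 1).all()

    def test_cutoff_below_one_is_an_error(self):
        with pytest.raises(ValueError):
            nhobs.classify_long_stay_method2(day_grid(10), cutoff=0)

    def test_short_cohorts_are_invisible_to_the_cutoff_but_not_to_observability(self):
        """Episodes under 101 days select nobody under the cutoff rule while
        still contributing observable person-time."""
        g = day_grid(60, snf_days=range(1, 11))
        cls = nhobs.classify_long_stay_method2(g)
        assert (cls["long_stay"] == 0).all()
        assert len(nhobs.select_observable_days(g)) == 50


class TestCompareAlgorithms:
    def test_snf_before_the_cutoff_leaves_long_stay_time_fully_observable(self):
        g = pd.concat([
            day_grid(150, rid="A", eid="A:001", snf_days=range(1, 21)),
            day_grid(120, rid="B", eid="B:001", snf_days=range(1, 21)),
        ], ignore_index=True)
        obs = nhobs.select_observable_days(g)
        cls = nhobs.classify_long_stay_method2(g)
        # day 101 falls on 2016-04-10 for both episodes
        out = nhobs.compare_algorithms(
            g, {"admission_assessment": obs}, cls, "2016-04")
        ls = out[out["algorithm"] == "long_stay_101d"].iloc[0]
        assert ls["unobservable_share"] == 0.0
        assert ls["n_residents"] == 2

    def test_counts_are_per_algorithm_and_per_month(self):
        g = day_grid(150, snf_days=range(1, 21))
        obs = nhobs.select_observable_days(g)
        cls = nhobs.classify_long_stay_method2(g)
        out = nhobs.compare_algorithms(g, {"entry": obs}, cls, "2016-01")
        entry = out[out["algorithm"] == "entry"].iloc[0]
        assert entry["n_days"] == 11  # Jan 21-31 observable
        ls = out[out["algorithm"] == "long_stay_101d"].iloc[0]
        assert ls["n_days"] == 0  # cutoff day falls in April

    def test_month_with_no_qualifying_days_reports_zeros(self):
        g = day_grid(40, start="2016-01-15")
        obs = nhobs.select_observable_days(g)
        cls = nhobs.classify_long_stay_method2(g)
        out = nhobs.compare_algorithms(
            g.assign(date=g["date"]),  # grid spans Jan-Feb
            {"entry": obs.iloc[0:0]}, cls, "2016-02")
        assert out.loc[out["algorithm"] == "entry", "n_days"].iloc[0] == 0

    def test_month_outside_the_grid_is_an_error(self):
        g = day_grid(40)
        with pytest.raises(ValueError, match="outside"):
            nhobs.compare_algorithms(
                g, {}, nhobs.classify_long_stay_method2(g), "2019-01")


class TestPointPrevalence:
    obs = day_grid(31, enrolled=1)

    def disp(self, rows):
        df = pd.DataFrame(rows, columns=["resident_id", "fill_date",
                                         "days_supply", "drug_class"])
        df["fill_date"] = pd.to_datetime(df["fill_date"])
        return df

    def test_fill_on_an_observable_day_counts_the_resident(self):
        d = self.disp([("A", "2016-01-10", 30, "gabapentin")])
        assert nhobs.point_prevalence(d, self.obs, "2016-01") == 1.0

    def test_fill_covering_only_unobservable_days_does_not_count(self):
        g = day_grid(31, hosp_days=range(10, 20))
        obs = nhobs.select_observable_days(g)
        d = self.disp([("A", "2016-01-10", 5, "gabapentin")])  # inside hospital
        assert nhobs.point_prevalence(d, obs, "2016-01") == 0.0

    def test_no_dispensings_gives_zero(self):
        assert nhobs.point_prevalence(self.disp([]), self.obs, "2016-01") == 0.0

    def test_nonpositive_days_supply_is_rejected(self, caplog):
        d = self.disp([("A", "2016-01-10", 0, "gabapentin")])
        with caplog.at_level("ERROR", logger="nhobs.cohort_summaries"):
            assert nhobs.point_prevalence(d, self.obs, "2016-01") == 0.0
        assert any("nonpositive" in r.message for r in caplog.records)

    def test_no_observable_residents_gives_nan(self):
        d = self.disp([("A", "2016-01-10", 30, "gabapentin")])
        assert np.isnan(nhobs.point_prevalence(d, self.obs, "2016-03"))
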