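"""Episode construction rules: anchoring, the 30-day reentry window, merging,
study-end closure, and death truncation."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nhobs
from nhobs.episode_builder import merge_overlapping_episodes

from tests.oracles import (
    build_flagged_days,
    episode_day_set,
    interval_day_set,
    small_params,
)

END_2016 = dt.date(2016, 12, 31)


def mds(rows):
    df = pd.DataFrame(rows, columns=["resident_id", "record_kind",
                                     "event_date", "disposition_code"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["disposition_code"] = df["disposition_code"].astype(float)
    return df


def test_entry_discharge_pair_is_one_episode():
    eps = nhobs.build_entry_episodes(
        mds([("A", "entry", "2015-03-01", None),
             ("A", "discharge", "2015-04-15", 10)]),
        dt.date(2015, 12, 31))
    assert len(eps) == 1
    row = eps.iloc[0]
    assert row["start_date"] == pd.Timestamp("2015-03-01")
    assert row["end_date"] == pd.Timestamp("2015-04-15")
    assert row["end_reason"] == "final_discharge"


def test_entry_without_discharge_closes_at_study_end():
    eps = nhobs.build_entry_episodes(
        mds([("A", "entry", "2020-11-01", None)]), dt.date(2020, 12, 31))
    assert eps.iloc[0]["end_date"] == pd.Timestamp("2020-12-31")
    assert eps.iloc[0]["end_reason"] == "study_end"


def test_two_entries_before_one_discharge_merge_to_the_day_set_union():
    records = mds([
        ("A", "entry", "2016-01-01", None),
        ("A", "entry", "2016-01-10", None),
        ("A", "discharge", "2016-02-01", 10),
    ])
    eps = merge_overlapping_episodes(
        nhobs.build_entry_episodes(records, END_2016))
    expected = interval_day_set([
        (pd.Timestamp("2016-01-01"), pd.Timestamp("2016-02-01")),
        (pd.Timestamp("2016-01-10"), pd.Timestamp("2016-02-01")),
    ])
    got = {d for _, d in episode_day_set(eps)}
    assert got == expected
    assert len(eps) == 1


class TestAdmissionAnchoredReentryRule:
    base = [
        ("A", "entry", "2016-01-01", None),
        ("A", "admission_assessment", "2016-01-05", None),
        ("A", "discharge", "2016-03-01", 11),
    ]

    def build(self, extra):
        return nhobs.build_admission_episodes(mds(self.base + extra), END_2016)

    def test_reentry_within_30_days_continues_the_episode(self):
        eps = self.build([("A", "entry", "2016-03-25", None),  # 24-day gap
                          ("A", "discharge", "2016-06-01", 10)])
        assert len(eps) == 1
        assert eps.iloc[0]["start_date"] == pd.Timestamp("2016-01-01")
        assert eps.iloc[0]["end_date"] == pd.Timestamp("2016-06-01")
        assert eps.iloc[0]["end_reason"] == "final_discharge"

    def test_reentry_beyond_30_days_ends_the_episode_at_the_discharge(self):
        eps = self.build([("A", "entry", "2016-04-05", None),  # 35-day gap
                          ("A", "discharge", "2016-06-01", 10)])
        assert len(eps) == 1  # no new admission assessment -> no new episode
        assert eps.iloc[0]["end_date"] == pd.Timestamp("2016-03-01")
        assert eps.iloc[0]["end_reason"] == "reentry_window_expired"

    def test_gap_of_exactly_30_days_is_still_the_same_episode(self):
        # one-line oracle for the boundary: (reentry - discharge).days <= 30
        reentry = pd.Timestamp("2016-03-31")
        assert (reentry - pd.Timestamp("2016-03-01")).days <= 30
        eps = self.build([("A", "entry", "2016-03-31", None),
                          ("A", "discharge", "2016-06-01", 10)])
        assert len(eps) == 1
        assert eps.iloc[0]["end_date"] == pd.Timestamp("2016-06-01")

    def test_codes_10_and_12_always_end_the_episode(self):
        for code in (10, 12):
            eps = nhobs.build_admission_episodes(
                mds([("A", "entry", "2016-01-01", None),
                     ("A", "admission_assessment", "2016-01-02", None),
                     ("A", "discharge", "2016-02-01", code),
                     ("A", "entry", "2016-02-10", None)]),
                END_2016)
            assert eps.iloc[0]["end_date"] == pd.Timestamp("2016-02-01")
            assert eps.iloc[0]["end_reason"] == "final_discharge"

    def test_second_episode_requires_a_new_admission_assessment(self):
        eps = self.build([
            ("A", "entry", "2016-04-05", None),
            ("A", "admission_assessment", "2016-04-05", None),
            ("A", "discharge", "2016-06-01", 10),
        ])
        assert len(eps) == 2
        assert eps.iloc[1]["start_date"] == pd.Timestamp("2016-04-05")
        assert eps.iloc[1]["end_date"] == pd.Timestamp("2016-06-01")


def test_overlap_merge_uses_first_entry_and_last_discharge():
    lt = nhobs.make_fixture("overlap_merge")
    entry_eps = nhobs.build_episodes(lt.mds, lt.study_end, anchor="entry")
    assert len(entry_eps) == 1
    assert int(entry_eps.iloc[0]["n_days"]) == \
        nhobs.FIXTURE_EXPECTATIONS["overlap_merge"]["entry_anchored_days"]
    adm_eps = nhobs.build_episodes(lt.mds, lt.study_end)
    assert int(adm_eps["n_days"].sum()) == \
        nhobs.FIXTURE_EXPECTATIONS["overlap_merge"]["admission_anchored_days"]


def episodes_frame(intervals, rid="A", anchor="entry"):
    rows = [{
        "resident_id": rid, "episode_id": None, "anchor": anchor,
        "start_date": pd.Timestamp(a), "end_date": pd.Timestamp(b),
        "end_reason": "final_discharge", "admission_assessment_date": pd.NaT,
        "n_days": (pd.Timestamp(b) - pd.Timestamp(a)).days + 1,
    } for a, b in intervals]
    return pd.DataFrame(rows)


def test_disjoint_episodes_stay_separate():
    eps = merge_overlapping_episodes(
        episodes_frame([("2016-01-01", "2016-01-10"),
                        ("2016-02-01", "2016-02-05")]))
    assert len(eps) == 2


@given(st.lists(
    st.tuples(st.integers(0, 120), st.integers(0, 40)), min_size=1, max_size=12))
def test_merge_matches_day_set_union_and_is_idempotent(spans):
    origin = pd.Timestamp("2016-01-01")
    intervals = [
        (origin + pd.Timedelta(days=s), origin + pd.Timedelta(days=s + w))
        for s, w in spans
    ]
    eps = episodes_frame(intervals)
    merged = merge_overlapping_episodes(eps)
    # day-set equality with the brute-force union
    got = {d for _, d in episode_day_set(merged)}
    assert got == interval_day_set(intervals)
    # pairwise disjoint
    m = merged.sort_values("start_date")
    assert (m["start_date"].iloc[1:].to_numpy()
            > m["end_date"].iloc[:-1].to_numpy()).all()
    # idempotent
    pd.testing.assert_frame_equal(
        merge_overlapping_episodes(merged).reset_index(drop=True),
        merged.reset_index(drop=True))
    # order-insensitive
    shuffled = eps.sample(frac=1, random_state=0)
    pd.testing.assert_frame_equal(
        merge_overlapping_episodes(shuffled).reset_index(drop=True),
        merged.reset_index(drop=True))


class TestFinalize:
    def test_death_truncates_the_episode(self):
        eps = episodes_frame([("2016-03-01", "2016-06-01")])
        out = nhobs.finalize_episodes(
            eps, {"A": pd.Timestamp("2016-04-10")}, END_2016)
        assert out.iloc[0]["end_date"] == pd.Timestamp("2016-04-10")
        assert out.iloc[0]["end_reason"] == "death"

    def test_death_after_episode_leaves_it_unchanged(self):
        eps = episodes_frame([("2016-03-01", "2016-06-01")])
        out = nhobs.finalize_episodes(
            eps, {"A": pd.Timestamp("2016-07-01")}, END_2016)
        assert out.iloc[0]["end_date"] == pd.Timestamp("2016-06-01")
        assert out.iloc[0]["end_reason"] == "final_discharge"

    def test_death_before_start_drops_the_episode_with_a_warning(self, caplog):
        eps = episodes_frame([("2016-03-01", "2016-06-01")])
        with caplog.at_level("WARNING", logger="nhobs.episode_builder"):
            out = nhobs.finalize_episodes(
                eps, {"A": pd.Timestamp("2016-01-15")}, END_2016)
        assert out.empty
        assert any("death" in r.message for r in caplog.records)

    def test_open_episodes_are_clipped_to_study_end(self):
        eps = episodes_frame([("2016-11-01", "2017-03-01")])
        out = nhobs.finalize_episodes(eps, {}, END_2016)
        assert out.iloc[0]["end_date"] == pd.Timestamp(END_2016)
        assert out.iloc[0]["end_reason"] == "study_end"


def test_end_reasons_partition_the_episodes(small_cohort):
    eps = nhobs.build_episodes(
        small_cohort.mds, small_cohort.study_end,
        deaths=small_cohort.deaths_map(), study_start=small_cohort.study_start)
    reasons = {"final_discharge", "reentry_window_expired", "study_end", "death"}
    assert set(eps["end_reason"].unique()) <= reasons
    assert eps["end_reason"].value_counts().sum() == len(eps)


@pytest.mark.parametrize("seed", [0, 4, 9])
def test_admission_days_lie_within_entry_days_up_to_bridged_gaps(seed):
    """Admission anchoring restricts entry-anchored NH time, except that a
    bridged code-11 reentry keeps its out-of-facility gap days in the span."""
    lt = nhobs.generate_cohort(small_params(seed, n_residents=20,
                                            reentry_prob=0.6))
    entry_eps, _ = build_flagged_days(lt, anchor="entry")
    entry_days = episode_day_set(entry_eps)

    adm = nhobs.build_admission_episodes(lt.mds, lt.study_end)
    gap_days = set()
    for rec in adm.itertuples():
        for g0, g1 in rec.gap_days:
            for d in pd.date_range(g0, g1):
                gap_days.add((rec.resident_id, d))
    adm_final = nhobs.build_episodes(lt.mds, lt.study_end,
                                     deaths=lt.deaths_map(),
                                     study_start=lt.study_start)
    assert episode_day_set(adm_final) <= entry_days | gap_days

    # with gap days excluded, containment is strict
    adm_nogap = nhobs.build_episodes(
        lt.mds, lt.study_end, deaths=lt.deaths_map(),
        study_start=lt.study_start, drop_out_of_facility_gaps=True)
    assert episode_day_set(adm_nogap) <= entry_days
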