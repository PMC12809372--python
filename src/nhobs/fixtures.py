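"""Hand-auditable fixture cohorts with documented expected results.

Each fixture is at most a handful of residents and exercises one rule of the
observability pipeline.  The expected observable-day counts (computed by hand
from the stated conventions: NH episodes are closed date intervals with the
entry date as day 1; Part A stays cover the half-open span [admit, discharge))
are recorded in :data:`FIXTURE_EXPECTATIONS` next to each builder and frozen
into the test suite.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    DEATH_COLUMNS,
    DISPENSING_COLUMNS,
    ENROLLMENT_COLUMNS,
    MDS_COLUMNS,
    STAY_COLUMNS,
    LinkedTables,
    _empty_tables,
)


def _tables(
    start: dt.date,
    end: dt.date,
    mds_rows: list[tuple],
    stay_rows: list[tuple] | None = None,
    death_rows: list[tuple] | None = None,
    disp_rows: list[tuple] | None = None,
    enrollment: pd.DataFrame | None = None,
) -> LinkedTables:
    base = _empty_tables(start, end)
    mds = pd.DataFrame(mds_rows, columns=MDS_COLUMNS)
    mds["event_date"] = pd.to_datetime(mds["event_date"])
    mds["disposition_code"] = mds["disposition_code"].astype(float)
    if enrollment is None:
        enrollment = _full_enrollment(sorted(mds["resident_id"].unique()), start, end)
    stays = base.part_a_stays
    if stay_rows:
        stays = pd.DataFrame(stay_rows, columns=STAY_COLUMNS)
        stays["admit_date"] = pd.to_datetime(stays["admit_date"])
        stays["discharge_date"] = pd.to_datetime(stays["discharge_date"])
        stays["length_of_stay"] = stays["length_of_stay"].astype(int)
    deaths = base.deaths
    if death_rows:
        deaths = pd.DataFrame(death_rows, columns=DEATH_COLUMNS)
        deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    disp = base.dispensings
    if disp_rows:
        disp = pd.DataFrame(disp_rows, columns=DISPENSING_COLUMNS)
        disp["fill_date"] = pd.to_datetime(disp["fill_date"])
    return LinkedTables(
        mds=mds, enrollment=enrollment, part_a_stays=stays,
        dispensings=disp, deaths=deaths, study_start=start, study_end=end,
    )


def _full_enrollment(
    resident_ids: list[str], start: dt.date, end: dt.date
) -> pd.DataFrame:
    """Complete FFS + Part D coverage, no managed care, for every month."""
    months = pd.period_range(start, end, freq="M").astype(str)
    frames = [
        pd.DataFrame({
            "resident_id": rid, "year_month": months,
            "part_a": np.int8(1), "part_b": np.int8(1),
            "part_d": np.int8(1), "managed_care": np.int8(0),
        })
        for rid in resident_ids
    ]
    if not frames:
        return pd.DataFrame(columns=ENROLLMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _figure1_schematic() -> LinkedTables:
    # One resident: 20-day SNF lead-in, a 5-day mid-stay hospitalization,
    # terminal code-10 discharge.  Episode 2016-03-01..2016-06-30 = 122 days;
    # SNF covers Mar 1-20, hospital May 10-14; observable = 122-20-5 = 97
    # days in two runs of 50 (Mar 21-May 9) and 47 (May 15-Jun 30).
    rows = [
        ("F1", "entry", "2016-03-01", None),
        ("F1", "admission_assessment", "2016-03-03", None),
        ("F1", "discharge", "2016-06-30", 10),
    ]
    stays = [
        ("F1", "snf", "2016-03-01", "2016-03-21", 20),
        ("F1", "inpatient", "2016-05-10", "2016-05-15", 5),
    ]
    return _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows, stays)


def _reentry_30d() -> LinkedTables:
    # R1: code-11 discharge then reentry exactly 30 days later -> same
    # episode, 2016-01-01..2016-04-30 = 121 days.
    # R2: identical but the return comes 31 days later -> first episode ends
    # at the code-11 discharge (32 days); a new admission assessment starts a
    # second episode 2016-03-03..2016-04-30 (59 days).
    rows = [
        ("R1", "entry", "2016-01-01", None),
        ("R1", "admission_assessment", "2016-01-01", None),
        ("R1", "discharge", "2016-02-01", 11),
        ("R1", "entry", "2016-03-02", None),
        ("R1", "discharge", "2016-04-30", 10),
        ("R2", "entry", "2016-01-01", None),
        ("R2", "admission_assessment", "2016-01-01", None),
        ("R2", "discharge", "2016-02-01", 11),
        ("R2", "entry", "2016-03-03", None),
        ("R2", "admission_assessment", "2016-03-03", None),
        ("R2", "discharge", "2016-04-30", 10),
    ]
    return _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows)


def _overlap_merge() -> LinkedTables:
    # Two entry/discharge pairs whose second entry (Jan 20) precedes the
    # first discharge (Jan 31): entry-anchored episodes merge to
    # 2016-01-01..2016-02-10 = 41 days.  Only the first pair carries an
    # admission assessment, so the admission-anchored episode is
    # 2016-01-01..2016-01-31 = 31 days.
    rows = [
        ("O1", "entry", "2016-01-01", None),
        ("O1", "admission_assessment", "2016-01-02", None),
        ("O1", "discharge", "2016-01-31", 10),
        ("O1", "entry", "2016-01-20", None),
        ("O1", "discharge", "2016-02-10", 10),
    ]
    return _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows)


def _open_episode() -> LinkedTables:
    # Entry with no discharge: episode runs to study end,
    # 2016-10-01..2016-12-31 = 92 days, end_reason study_end.
    rows = [
        ("P1", "entry", "2016-10-01", None),
        ("P1", "admission_assessment", "2016-10-01", None),
    ]
    return _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows)


def _death_truncation() -> LinkedTables:
    # D1: discharge recorded 2016-03-31 but death 2016-02-15 truncates the
    # episode to 46 days.  D2: open episode truncated at death
    # (2016-06-01..2016-08-15 = 76 days).
    rows = [
        ("D1", "entry", "2016-01-01", None),
        ("D1", "admission_assessment", "2016-01-01", None),
        ("D1", "discharge", "2016-03-31", 10),
        ("D2", "entry", "2016-06-01", None),
        ("D2", "admission_assessment", "2016-06-02", None),
    ]
    deaths = [("D1", "2016-02-15"), ("D2", "2016-08-15")]
    return _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows,
                   death_rows=deaths)


def _missing_discharge() -> LinkedTables:
    # One SNF stay with the discharge date absent and LOS 14: imputation
    # restores 2016-01-15, flagging Jan 1-14.  Episode 2016-01-01..2016-03-01
    # = 61 days; observable = 61 - 14 = 47.
    rows = [
        ("M1", "entry", "2016-01-01", None),
        ("M1", "admission_assessment", "2016-01-01", None),
        ("M1", "discharge", "2016-03-01", 10),
    ]
    stays = [("M1", "snf", "2016-01-01", None, 14)]
    lt = _tables(dt.date(2016, 1, 1), dt.date(2016, 12, 31), rows, stays)
    lt.part_a_stays["discharge_date"] = pd.to_datetime(
        lt.part_a_stays["discharge_date"])
    return lt


_FIXTURES = {
    "figure1_schematic": _figure1_schematic,
    "reentry_30d": _reentry_30d,
    "overlap_merge": _overlap_merge,
    "open_episode": _open_episode,
    "death_truncation": _death_truncation,
    "missing_discharge": _missing_discharge,
}

#: Hand-computed expectations (admission-assessment anchor, default
#: conventions) frozen beside each fixture; the test suite asserts these.
FIXTURE_EXPECTATIONS: dict[str, dict[str, object]] = {
    "figure1_schematic": {
        "n_episodes": 1, "nh_days": 122, "snf_days": 20, "hospital_days": 5,
        "observable_days": 97, "observable_episode_lengths": [50, 47],
    },
    "reentry_30d": {
        "n_episodes": 3, "episode_lengths": [121, 32, 59],
        "nh_days": 212, "observable_days": 212,
    },
    "overlap_merge": {
        "entry_anchored_days": 41, "admission_anchored_days": 31,
        "observable_days": 31,
    },
    "open_episode": {
        "n_episodes": 1, "nh_days": 92, "end_reason": "study_end",
        "observable_days": 92,
    },
    "death_truncation": {
        "n_episodes": 2, "episode_lengths": [46, 76], "nh_days": 122,
        "end_reasons": ["death", "death"], "observable_days": 122,
    },
    "missing_discharge": {
        "n_episodes": 1, "nh_days": 61, "snf_days": 14, "observable_days": 47,
        "imputed_discharge": "2016-01-15",
    },
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str) -> LinkedTables:
    """Return the named fixture cohort (see :data:`FIXTURE_EXPECTATIONS`)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture '{name}'; available: {', '.join(fixture_names())}"
        ) from None
    return builder()
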