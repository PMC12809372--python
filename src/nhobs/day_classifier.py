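"""Expand NH episodes to a resident-day grid and set observability flags.

Each NH day carries three binary flags: ``enrolled`` (Medicare Parts A, B and
D with no managed-care month — the days on which Part D dispensings can
appear in claims), ``snf`` (the day falls under a Part A post-acute skilled
nursing stay, whose bundled payment hides dispensings), and ``hospital``
(inpatient stay).  A day may be both SNF and hospital flagged.

Conventions:

* enrollment is judged at calendar-month granularity (the layout of the
  Medicare Beneficiary Summary File); months absent from the table count as
  unenrolled — observability is never assumed without evidence.  A
  daily-interval enrollment input is also accepted.
* Part A stays cover the half-open span [admit, discharge), so the recorded
  length of stay equals discharge minus admit and the discharge day belongs
  to the next care setting.  ``include_discharge_day=True`` switches to the
  closed convention for sensitivity analyses.
* missing Part A discharge dates are imputed as admit + length of stay.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAY_COLUMNS = ["resident_id", "episode_id", "date", "day_index"]
FLAG_COLUMNS = ["enrolled", "snf", "hospital"]


def impute_part_a_discharge(
    stays: pd.DataFrame, *, on_unimputable: str = "drop"
) -> pd.DataFrame:
    """Fill missing discharge dates as ``admit_date + length_of_stay``.

    Rows with both fields present are unchanged.  Rows missing both the
    discharge date and the length of stay cannot be placed on the day grid:
    they are dropped with a logged error record (or raised when
    ``on_unimputable='raise'``).
    """
    stays = stays.copy()
    missing = stays["discharge_date"].isna()
    if not missing.any():
        return stays
    bad = missing & stays["length_of_stay"].isna()
    if bad.any():
        msg = (f"{int(bad.sum())} Part A stays missing both discharge date "
               f"and length of stay (rows {list(stays.index[bad])})")
        if on_unimputable == "raise":
            raise ValueError(msg)
        log.error("%s; rows dropped", msg)
        stays = stays[~bad]
        missing = stays["discharge_date"].isna()
    stays.loc[missing, "discharge_date"] = (
        stays.loc[missing, "admit_date"]
        + pd.to_timedelta(stays.loc[missing, "length_of_stay"], unit="D")
    )
    log.info("imputed %d missing Part A discharge dates from length of stay",
             int(missing.sum()))
    return stays


def expand_to_days(episodes: pd.DataFrame) -> pd.DataFrame:
    """One row per calendar day per episode; day 1 is the episode start.

    Requires finalized, per-resident disjoint episodes (merge first);
    overlapping episodes raise a precondition error.
    """
    if episodes.empty:
        return pd.DataFrame({
            "resident_id": pd.Series(dtype=object),
            "episode_id": pd.Series(dtype=object),
            "date": pd.Series(dtype="datetime64[ns]"),
            "day_index": pd.Series(dtype=np.int64),
        })
    eps = episodes.sort_values(["resident_id", "start_date"], kind="mergesort")
    same_res = eps["resident_id"].eq(eps["resident_id"].shift())
    overlap = same_res & (eps["start_date"] <= eps["end_date"].shift())
    if overlap.any():
        raise ValueError(
            "overlapping episodes for "
            f"{sorted(eps.loc[overlap, 'resident_id'].unique())}; merge first"
        )
    lengths = (eps["end_date"] - eps["start_date"]).dt.days.to_numpy() + 1
    if (lengths < 1).any():
        raise ValueError("episode with end_date before start_date")
    idx = np.repeat(np.arange(len(eps)), lengths)
    day_index = np.concatenate([np.arange(1, n + 1) for n in lengths])
    days = pd.DataFrame({
        "resident_id": eps["resident_id"].to_numpy()[idx],
        "episode_id": eps["episode_id"].to_numpy()[idx],
        "date": eps["start_date"].to_numpy()[idx]
        + (day_index - 1).astype("timedelta64[D]"),
        "day_index": day_index.astype(np.int64),
    })
    return days


def _month_key(dates: pd.Series) -> pd.Series:
    return dates.dt.to_period("M").astype(str)


def flag_enrollment(
    days: pd.DataFrame,
    enrollment: pd.DataFrame,
    *,
    granularity: str = "month",
) -> pd.DataFrame:
    """Set ``enrolled=1`` on days meeting the Parts A+B+D, no-managed-care test.

    With ``granularity='month'`` (default) the enrollment table has one row
    per resident-month; duplicate resident-months raise an error naming them.
    With ``granularity='day'`` the table instead carries ``start_date`` /
    ``end_date`` interval rows and the flags apply to days inside qualifying
    intervals.
    """
    days = days.copy()
    if granularity == "day":
        ok = enrollment[
            (enrollment["part_a"] == 1) & (enrollment["part_b"] == 1)
            & (enrollment["part_d"] == 1) & (enrollment["managed_care"] == 0)
        ]
        covered = _interval_day_index(ok, "start_date", "end_date", closed=True)
        key = pd.MultiIndex.from_arrays([days["resident_id"], days["date"]])
        days["enrolled"] = key.isin(covered).astype(np.int8)
        return days
    if granularity != "month":
        raise ValueError("granularity must be 'month' or 'day'")

    dup = enrollment.duplicated(["resident_id", "year_month"])
    if dup.any():
        pairs = (enrollment.loc[dup, ["resident_id", "year_month"]]
                 .drop_duplicates().itertuples(index=False))
        raise ValueError(
            "duplicate enrollment rows for resident-months: "
            + ", ".join(f"{r}/{m}" for r, m in pairs)
        )
    enr = enrollment.copy()
    enr["year_month"] = enr["year_month"].astype(str)
    enr["_ok"] = (
        (enr["part_a"] == 1) & (enr["part_b"] == 1)
        & (enr["part_d"] == 1) & (enr["managed_care"] == 0)
    ).astype(np.int8)
    merged = days.assign(year_month=_month_key(days["date"])).merge(
        enr[["resident_id", "year_month", "_ok"]],
        on=["resident_id", "year_month"], how="left",
    )
    days["enrolled"] = merged["_ok"].fillna(0).astype(np.int8).to_numpy()
    return days


def _interval_day_index(
    frame: pd.DataFrame, start_col: str, end_col: str, *, closed: bool
) -> pd.MultiIndex:
    """Expand (resident, interval) rows to a unique (resident, day) index."""
    if frame.empty:
        return pd.MultiIndex.from_arrays([[], pd.DatetimeIndex([])])
    lengths = (frame[end_col] - frame[start_col]).dt.days.to_numpy()
    lengths = lengths + 1 if closed else lengths
    keep = lengths > 0
    frame, lengths = frame[keep], lengths[keep]
    if not len(frame):
        return pd.MultiIndex.from_arrays([[], pd.DatetimeIndex([])])
    idx = np.repeat(np.arange(len(frame)), lengths)
    offs = np.concatenate([np.arange(n) for n in lengths])
    rid = frame["resident_id"].to_numpy()[idx]
    dates = frame[start_col].to_numpy()[idx] + offs.astype("timedelta64[D]")
    return pd.MultiIndex.from_arrays([rid, dates]).drop_duplicates()


def flag_part_a_stays(
    days: pd.DataFrame,
    stays: pd.DataFrame,
    stay_type: str,
    *,
    include_discharge_day: bool = False,
) -> pd.DataFrame:
    """Set the ``snf`` or ``hospital`` flag where stay days meet the grid.

    Overlapping stays of the same type act as a union.  Stays require imputed
    discharge dates (precondition); stays whose discharge precedes admission
    are rejected with a logged error record.
    """
    if stay_type not in ("snf", "inpatient"):
        raise ValueError("stay_type must be 'snf' or 'inpatient'")
    col = "snf" if stay_type == "snf" else "hospital"
    days = days.copy()
    sub = stays[stays["stay_type"] == stay_type]
    if sub["discharge_date"].isna().any():
        raise ValueError(
            "stays contain missing discharge dates; run impute_part_a_discharge first"
        )
    bad = sub["discharge_date"] < sub["admit_date"]
    if bad.any():
        log.error("rejected %d %s stays with discharge before admission (rows %s)",
                  int(bad.sum()), stay_type, list(sub.index[bad]))
        sub = sub[~bad]
    covered = _interval_day_index(sub, "admit_date", "discharge_date",
                                  closed=include_discharge_day)
    key = pd.MultiIndex.from_arrays([days["resident_id"], days["date"]])
    days[col] = key.isin(covered).astype(np.int8)
    return days


def flag_days(
    days: pd.DataFrame,
    enrollment: pd.DataFrame,
    stays: pd.DataFrame,
    *,
    enrollment_granularity: str = "month",
    include_discharge_day: bool = False,
) -> pd.DataFrame:
    """Apply all three flagging steps (order has no effect on the result)."""
    days = flag_enrollment(days, enrollment, granularity=enrollment_granularity)
    days = flag_part_a_stays(days, stays, "snf",
                             include_discharge_day=include_discharge_day)
    days = flag_part_a_stays(days, stays, "inpatient",
                             include_discharge_day=include_discharge_day)
    return days
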