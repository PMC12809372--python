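"""Construct nursing-home episodes from MDS-style tracking records.

Two anchorings are supported.  *Entry-anchored* episodes pair each MDS entry
record with the next discharge record on or after it (an entry with no
subsequent discharge stays open and is closed at the study end).
*Admission-assessment-anchored* episodes require an admission assessment and
end at a discharge with disposition code 10 or 12, or at a code-11
(return-anticipated) discharge that is not followed by a reentry within 30
days; a reentry at most 30 days after a code-11 discharge continues the same
episode, per CMS reentry guidance.

Episodes are closed date intervals: the entry date is NH day 1 and the end
date counts as an NH day.  Overlapping episodes of the same anchor type are
merged span-wise (first entry to last discharge), and all episodes are
truncated at the recorded date of death.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "resident_id", "episode_id", "anchor", "start_date", "end_date",
    "end_reason", "admission_assessment_date", "n_days",
]

#: maximum out-of-facility gap (days) a code-11 discharge/reentry pair may
#: bridge while remaining one episode
REENTRY_WINDOW_DAYS = 30

_KIND_ORDER = {"entry": 0, "admission_assessment": 1, "other_assessment": 2,
               "discharge": 3}


def _empty_episodes() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in EPISODE_COLUMNS})
    for c in ("start_date", "end_date", "admission_assessment_date"):
        df[c] = pd.Series(dtype="datetime64[ns]")
    df["n_days"] = pd.Series(dtype=np.int64)
    return df


def _episodes_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return _empty_episodes()
    df = pd.DataFrame(rows)
    if "episode_id" not in df.columns:
        df["episode_id"] = None
    df["n_days"] = (df["end_date"] - df["start_date"]).dt.days + 1
    cols = EPISODE_COLUMNS + (["gap_days"] if "gap_days" in df.columns else [])
    return df[cols]


def _resident_records(mds: pd.DataFrame, study_end: pd.Timestamp):
    """Yield per-resident record lists sorted by (date, kind precedence)."""
    n_late = int((mds["event_date"] > study_end).sum())
    if n_late:
        log.info("ignoring %d MDS records dated after study end", n_late)
        mds = mds[mds["event_date"] <= study_end]
    for rid, g in mds.groupby("resident_id", sort=True):
        recs = sorted(
            zip(g["event_date"], g["record_kind"], g["disposition_code"]),
            key=lambda r: (r[0], _KIND_ORDER.get(r[1], 2)),
        )
        yield rid, recs


def build_entry_episodes(mds: pd.DataFrame, study_end: dt.date) -> pd.DataFrame:
    """One episode per entry record, ending at the next discharge on/after it.

    Entries with no subsequent discharge end at ``study_end`` with
    ``end_reason='study_end'``.  Orphan discharges (no entry on or before
    them) are counted and logged, not raised.
    """
    study_end = pd.Timestamp(study_end)
    rows: list[dict] = []
    orphans = 0
    for rid, recs in _resident_records(mds, study_end):
        entries = [d for d, k, _ in recs if k == "entry"]
        discharges = [d for d, k, _ in recs if k == "discharge"]
        if discharges and (not entries or min(discharges) < min(entries)):
            orphans += sum(1 for d in discharges
                           if not entries or d < min(entries))
        # pair each entry with the first unconsumed discharge on/after it, so
        # interleaved entry/discharge pairs keep their own endpoints; when all
        # later discharges are consumed (two entries sharing one discharge)
        # the entry reuses the earliest discharge on/after it, and an entry
        # with no later discharge at all stays open until study end
        next_free = 0
        for e in entries:
            while next_free < len(discharges) and discharges[next_free] < e:
                next_free += 1
            if next_free < len(discharges):
                end, reason = discharges[next_free], "final_discharge"
                next_free += 1
            else:
                later = [d for d in discharges if d >= e]
                if later:
                    end, reason = later[0], "final_discharge"
                else:
                    end, reason = study_end, "study_end"
            rows.append({
                "resident_id": rid, "episode_id": None, "anchor": "entry",
                "start_date": e, "end_date": end, "end_reason": reason,
                "admission_assessment_date": pd.NaT,
            })
    if orphans:
        log.info("skipped %d discharge records with no preceding entry", orphans)
    return _episodes_frame(rows)


def build_admission_episodes(
    mds: pd.DataFrame,
    study_end: dt.date,
    *,
    admission_day_one: str = "entry",
) -> pd.DataFrame:
    """Episodes anchored on admission assessments with the 30-day reentry rule.

    ``admission_day_one`` selects whether day 1 of the episode is the nearest
    entry record on/before the anchoring assessment (``'entry'``, the
    default, falling back to the assessment date when no entry exists) or the
    assessment date itself (``'assessment'``).

    Out-of-facility gap days inside a bridged code-11/reentry pair are kept
    in the episode span; the per-episode ``gap_days`` column records them so
    they can be excluded via ``split_gap_segments``.
    """
    if admission_day_one not in ("entry", "assessment"):
        raise ValueError("admission_day_one must be 'entry' or 'assessment'")
    study_end = pd.Timestamp(study_end)
    rows: list[dict] = []
    for rid, recs in _resident_records(mds, study_end):
        entries = [d for d, k, _ in recs if k == "entry"]
        aas = [d for d, k, _ in recs if k == "admission_assessment"]
        discharges = [(d, int(c)) for d, k, c in recs
                      if k == "discharge" and pd.notna(c)]
        prev_end: pd.Timestamp | None = None
        for aa in aas:
            if prev_end is not None and aa <= prev_end:
                continue  # assessment inside an already-built episode
            cands = [e for e in entries
                     if e <= aa and (prev_end is None or e > prev_end)]
            start = max(cands) if cands else aa
            if admission_day_one == "assessment":
                start = aa
            end: pd.Timestamp | None = None
            reason = "study_end"
            gaps: list[tuple[pd.Timestamp, pd.Timestamp]] = []
            di = 0
            cursor = start
            while di < len(discharges):
                ddate, code = discharges[di]
                if ddate < cursor:
                    di += 1
                    continue
                if code in (10, 12):
                    end, reason = ddate, "final_discharge"
                    break
                # code 11: look for a reentry within the 30-day window
                reentries = [e for e in entries if e > ddate]
                if reentries and (reentries[0] - ddate).days <= REENTRY_WINDOW_DAYS:
                    re = reentries[0]
                    if (re - ddate).days >= 2:
                        gaps.append((ddate + pd.Timedelta(days=1),
                                     re - pd.Timedelta(days=1)))
                    cursor = re  # skip discharges inside the gap
                    di += 1
                    continue
                end, reason = ddate, "reentry_window_expired"
                break
            if end is None:
                end = study_end
            rows.append({
                "resident_id": rid, "episode_id": None,
                "anchor": "admission_assessment",
                "start_date": start, "end_date": end, "end_reason": reason,
                "admission_assessment_date": aa,
                "gap_days": gaps,
            })
            prev_end = end
    return _episodes_frame(rows)


def split_gap_segments(episodes: pd.DataFrame) -> pd.DataFrame:
    """Exclude bridged out-of-facility gap days by splitting episodes.

    Interior segments created at a gap boundary carry ``end_reason
    'gap_split'``; the final segment keeps the parent's end reason.  Used when
    ``drop_out_of_facility_gaps`` is enabled; the default pipeline keeps gap
    days in the span (downstream flags typically remove them anyway).
    """
    if "gap_days" not in episodes.columns:
        return episodes
    rows: list[dict] = []
    for rec in episodes.to_dict("records"):
        gaps = rec.pop("gap_days") or []
        if not gaps:
            rows.append(rec)
            continue
        seg_start = rec["start_date"]
        for g0, g1 in gaps:
            seg = dict(rec)
            seg["start_date"] = seg_start
            seg["end_date"] = g0 - pd.Timedelta(days=1)
            seg["end_reason"] = "gap_split"
            rows.append(seg)
            seg_start = g1 + pd.Timedelta(days=1)
        last = dict(rec)
        last["start_date"] = seg_start
        rows.append(last)
    return _episodes_frame(rows)


def apply_discharge_day_convention(
    episodes: pd.DataFrame, count_discharge_day: bool = True
) -> pd.DataFrame:
    """Optionally exclude the discharge date from final-discharge episodes."""
    if count_discharge_day:
        return episodes
    eps = episodes.copy()
    mask = eps["end_reason"] == "final_discharge"
    eps.loc[mask, "end_date"] = eps.loc[mask, "end_date"] - pd.Timedelta(days=1)
    dropped = (eps["end_date"] < eps["start_date"]).sum()
    if dropped:
        log.info("dropped %d one-day episodes under count_discharge_day=False",
                 dropped)
    eps = eps[eps["end_date"] >= eps["start_date"]].reset_index(drop=True)
    eps["n_days"] = (eps["end_date"] - eps["start_date"]).dt.days + 1
    return eps


def merge_overlapping_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping episodes per resident and anchor type.

    Episodes overlap when one starts on or before another's end date; the
    merged episode spans the first start to the last end of the overlap
    chain.  Adjacent-but-disjoint episodes (next start = end + 1 day) are
    kept separate.  Idempotent and insensitive to input order.
    """
    if episodes.empty:
        return episodes.copy()
    eps = episodes.sort_values(
        ["resident_id", "anchor", "start_date", "end_date"], kind="mergesort"
    )
    rows: list[dict] = []
    for (rid, anchor), g in eps.groupby(["resident_id", "anchor"], sort=True):
        cur: dict | None = None
        for rec in g.to_dict("records"):
            if cur is None:
                cur = dict(rec)
                continue
            if rec["start_date"] <= cur["end_date"]:
                if rec["end_date"] > cur["end_date"]:
                    cur["end_date"] = rec["end_date"]
                    cur["end_reason"] = rec["end_reason"]
                aa = [d for d in (cur["admission_assessment_date"],
                                  rec["admission_assessment_date"])
                      if pd.notna(d)]
                cur["admission_assessment_date"] = min(aa) if aa else pd.NaT
            else:
                rows.append(cur)
                cur = dict(rec)
        if cur is not None:
            rows.append(cur)
    out = _episodes_frame(rows)
    if "gap_days" in out.columns:
        out = out.drop(columns=["gap_days"])
    return out


def finalize_episodes(
    episodes: pd.DataFrame,
    deaths: Mapping[str, pd.Timestamp] | pd.DataFrame | None,
    study_end: dt.date,
    study_start: dt.date | None = None,
) -> pd.DataFrame:
    """Clip to the study window, truncate at death, and assign episode ids.

    Episodes ending after the recorded death date are truncated with
    ``end_reason='death'``; episodes starting after death are dropped with a
    logged warning.  Episode ids are ``<resident_id>:<k>`` with ``k`` ordered
    by start date, so they are stable under any partitioning of residents.
    """
    study_end = pd.Timestamp(study_end)
    if isinstance(deaths, pd.DataFrame):
        deaths = dict(zip(deaths["resident_id"], deaths["death_date"]))
    deaths = deaths or {}
    eps = episodes.copy()
    if "gap_days" in eps.columns:
        eps = eps.drop(columns=["gap_days"])
    if eps.empty:
        return _empty_episodes()

    if study_start is not None:
        start_ts = pd.Timestamp(study_start)
        eps = eps[eps["end_date"] >= start_ts]
        eps.loc[eps["start_date"] < start_ts, "start_date"] = start_ts
    eps = eps[eps["start_date"] <= study_end].copy()
    over = eps["end_date"] > study_end
    eps.loc[over, "end_date"] = study_end
    eps.loc[over, "end_reason"] = "study_end"

    death_dates = eps["resident_id"].map(
        lambda r: deaths.get(r, pd.NaT)).astype("datetime64[ns]")
    after_death = death_dates.notna() & (eps["start_date"] > death_dates)
    if after_death.any():
        log.warning("dropped %d episodes starting after the recorded death date",
                    int(after_death.sum()))
    eps = eps[~after_death].copy()
    death_dates = death_dates[~after_death]
    truncate = death_dates.notna() & (eps["end_date"] > death_dates)
    eps.loc[truncate, "end_date"] = death_dates[truncate]
    eps.loc[truncate, "end_reason"] = "death"

    eps = eps.sort_values(["resident_id", "start_date", "end_date"],
                          kind="mergesort").reset_index(drop=True)
    eps["episode_id"] = (
        eps["resident_id"] + ":"
        + (eps.groupby("resident_id").cumcount() + 1).astype(str).str.zfill(3)
    )
    eps["n_days"] = (eps["end_date"] - eps["start_date"]).dt.days + 1
    return eps[EPISODE_COLUMNS]


def build_episodes(
    mds: pd.DataFrame,
    study_end: dt.date,
    *,
    anchor: str = "admission_assessment",
    deaths: Mapping[str, pd.Timestamp] | pd.DataFrame | None = None,
    study_start: dt.date | None = None,
    admission_day_one: str = "entry",
    count_discharge_day: bool = True,
    drop_out_of_facility_gaps: bool = False,
) -> pd.DataFrame:
    """End-to-end episode construction: build, merge, finalize.

    Convenience wrapper running the full pipeline for one anchor type and
    returning finalized, disjoint, id-assigned episodes.
    """
    if anchor == "entry":
        eps = build_entry_episodes(mds, study_end)
    elif anchor == "admission_assessment":
        eps = build_admission_episodes(mds, study_end,
                                       admission_day_one=admission_day_one)
        if drop_out_of_facility_gaps:
            eps = split_gap_segments(eps)
    else:
        raise ValueError("anchor must be 'entry' or 'admission_assessment'")
    eps = apply_discharge_day_convention(eps, count_discharge_day)
    eps = merge_overlapping_episodes(eps)
    return finalize_episodes(eps, deaths, study_end, study_start)
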