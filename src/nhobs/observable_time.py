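"""Select observable medication-use days and rebuild contiguous episodes.

A nursing-home day is *observable medication-use time* when the resident is
FFS + Part D enrolled, not under bundled Part A skilled-nursing payment, and
not hospitalized — the days on which a dispensing can appear in Part D
claims.  Removing all other days and re-running the remaining dates through
run-length grouping yields maximal contiguous observable episodes, keyed to
the parent NH admission (observable episodes never bridge a removed day, and
never span two NH admissions even when adjacent in calendar time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .day_classifier import FLAG_COLUMNS

log = logging.getLogger(__name__)

OBSERVABLE_EPISODE_COLUMNS = [
    "resident_id", "episode_id", "obs_episode_id", "start_date", "end_date",
    "n_days",
]

#: Day-index bins used to report observability by time since NH admission.
TIME_BIN_LABELS = ["1–30", "31–60", "61–100", "101+"]
TIME_BIN_EDGES = [0, 30, 60, 100]


@dataclass(frozen=True)
class TimeBin:
    label: str
    lower: int
    upper: int | None  # inclusive; None = unbounded


DEFAULT_BINS = [
    TimeBin("1–30", 1, 30),
    TimeBin("31–60", 31, 60),
    TimeBin("61–100", 61, 100),
    TimeBin("101+", 101, None),
]


def _require_flags(days: pd.DataFrame) -> None:
    missing = [c for c in FLAG_COLUMNS if c not in days.columns]
    if missing:
        raise ValueError(f"day grid missing flag columns {missing}; "
                         "run the flagging steps first")


def observable_mask(days: pd.DataFrame) -> pd.Series:
    """Boolean predicate: enrolled and neither SNF-covered nor hospitalized."""
    _require_flags(days)
    return (days["enrolled"] == 1) & (days["snf"] == 0) & (days["hospital"] == 0)


def select_observable_days(days: pd.DataFrame) -> pd.DataFrame:
    """Drop unobservable days, logging removal counts per reason.

    A day removed for multiple reasons increments each reason's counter (SNF
    and hospital can coincide), while the unique-removal total counts each
    day once; SNF/hospital reasons are tallied among enrolled days, matching
    the stepwise accounting convention of the attrition table.
    """
    _require_flags(days)
    keep = observable_mask(days)
    enrolled = days["enrolled"] == 1
    log.info(
        "removed %d of %d NH days (unenrolled=%d, enrolled-SNF=%d, "
        "enrolled-hospital=%d; multi-reason days counted in each reason)",
        int((~keep).sum()), len(days), int((~enrolled).sum()),
        int((enrolled & (days["snf"] == 1)).sum()),
        int((enrolled & (days["hospital"] == 1)).sum()),
    )
    return days[keep].reset_index(drop=True)


def observable_run_ids(days: pd.DataFrame) -> pd.Series:
    """Run labels for maximal consecutive-date runs within (resident, episode).

    Input must already be restricted to observable days.  Returned series is
    aligned to a (resident_id, episode_id, date)-sorted copy of the input.
    """
    d = days.sort_values(["resident_id", "episode_id", "date"], kind="mergesort")
    new_run = (
        (d["resident_id"] != d["resident_id"].shift())
        | (d["episode_id"] != d["episode_id"].shift())
        | ((d["date"] - d["date"].shift()) != pd.Timedelta(days=1))
    )
    return new_run.cumsum()


def build_observable_episodes(days: pd.DataFrame) -> pd.DataFrame:
    """Collapse observable days into maximal contiguous observable episodes."""
    if days.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object)
                           for c in OBSERVABLE_EPISODE_COLUMNS})
        df["start_date"] = pd.Series(dtype="datetime64[ns]")
        df["end_date"] = pd.Series(dtype="datetime64[ns]")
        df["n_days"] = pd.Series(dtype=np.int64)
        return df
    d = days.sort_values(["resident_id", "episode_id", "date"],
                         kind="mergesort").reset_index(drop=True)
    runs = observable_run_ids(d).to_numpy()
    out = (
        d.assign(_run=runs)
        .groupby("_run", sort=True)
        .agg(
            resident_id=("resident_id", "first"),
            episode_id=("episode_id", "first"),
            start_date=("date", "first"),
            end_date=("date", "last"),
            n_days=("date", "size"),
        )
        .reset_index(drop=True)
    )
    out["obs_episode_id"] = (
        out["episode_id"] + ":"
        + (out.groupby("episode_id").cumcount() + 1).astype(str).str.zfill(2)
    )
    out["n_days"] = out["n_days"].astype(np.int64)
    return out[OBSERVABLE_EPISODE_COLUMNS]


def expand_observable_episodes(obs_episodes: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`build_observable_episodes` (round-trip identity)."""
    if obs_episodes.empty:
        return pd.DataFrame({
            "resident_id": pd.Series(dtype=object),
            "episode_id": pd.Series(dtype=object),
            "date": pd.Series(dtype="datetime64[ns]"),
        })
    lengths = obs_episodes["n_days"].to_numpy()
    idx = np.repeat(np.arange(len(obs_episodes)), lengths)
    offs = np.concatenate([np.arange(n) for n in lengths])
    return pd.DataFrame({
        "resident_id": obs_episodes["resident_id"].to_numpy()[idx],
        "episode_id": obs_episodes["episode_id"].to_numpy()[idx],
        "date": obs_episodes["start_date"].to_numpy()[idx]
        + offs.astype("timedelta64[D]"),
    })


def assign_time_bins(
    days: pd.DataFrame, bins: list[TimeBin] | None = None
) -> pd.DataFrame:
    """Label each day with its time-since-admission bin (day 1 = admission)."""
    bins = bins or DEFAULT_BINS
    days = days.copy()
    if (days["day_index"] < 1).any():
        raise ValueError("day_index must be >= 1")
    edges = [b.lower - 1 for b in bins] + [
        np.inf if bins[-1].upper is None else bins[-1].upper
    ]
    days["time_bin"] = pd.cut(
        days["day_index"], bins=edges, labels=[b.label for b in bins],
        right=True,
    )
    return days
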