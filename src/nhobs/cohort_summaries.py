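"""Reporting surface: stepwise attrition, long-stay comparator, prevalence.

``summarize_attrition`` mirrors the standard stepwise accounting of NH
observability pipelines: total NH days, days removed for non-enrollment,
enrolled days under SNF or hospital care (a single day can count toward
both), and the observable remainder — per time-since-admission bin and
overall.  Percentages are reported to one decimal, rounding half away from
zero, as ``100 x observable/enrolled`` and ``100 x observable/total``.

``classify_long_stay_method2`` implements the conventional length-of-stay
cutoff used to define "long-stay" NH residents (day 101 of the admission, a
convention driven by the 100-day Part A skilled-nursing benefit).  The
published "method 2" rules are not fully restated here, so this classifier
is a labeled approximation: an episode qualifies when it reaches the cutoff
day index, and long-stay person-time is attributed either from the cutoff
day onward (default) or to the whole episode.  It deliberately ignores
observability flags — quantifying how much long-stay person-time is in fact
medication-unobservable is the point of the comparison.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .observable_time import (
    DEFAULT_BINS,
    TimeBin,
    assign_time_bins,
    observable_mask,
    observable_run_ids,
)

log = logging.getLogger(__name__)

ATTRITION_COLUMNS = [
    "n_residents", "n_admission_episodes", "total_days",
    "unenrolled_days", "enrolled_days", "snf_days", "enrolled_not_snf_days",
    "hospital_days", "enrolled_not_hospital_days", "observable_days",
    "n_residents_observable", "n_admission_episodes_observable",
    "n_observable_episodes",
    "pct_observable_of_enrolled", "pct_observable_of_total",
]


def percent(numerator: float, denominator: float) -> float | None:
    """``100 x numerator/denominator`` to one decimal, half away from zero.

    Returns ``None`` (reported as absent, not zero) when the denominator is
    zero.
    """
    if denominator == 0:
        return None
    frac = Decimal(int(numerator)) / Decimal(int(denominator)) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _bin_stats(days: pd.DataFrame, obs_runs: pd.Series) -> dict:
    enrolled = days["enrolled"] == 1
    obs = observable_mask(days)
    stats = {
        "n_residents": days["resident_id"].nunique(),
        "n_admission_episodes": days["episode_id"].nunique(),
        "total_days": len(days),
        "unenrolled_days": int((~enrolled).sum()),
        "enrolled_days": int(enrolled.sum()),
        "snf_days": int((enrolled & (days["snf"] == 1)).sum()),
        "enrolled_not_snf_days": int((enrolled & (days["snf"] == 0)).sum()),
        "hospital_days": int((enrolled & (days["hospital"] == 1)).sum()),
        "enrolled_not_hospital_days": int(
            (enrolled & (days["hospital"] == 0)).sum()),
        "observable_days": int(obs.sum()),
        "n_residents_observable": days.loc[obs, "resident_id"].nunique(),
        "n_admission_episodes_observable": days.loc[obs, "episode_id"].nunique(),
        "n_observable_episodes": obs_runs[obs.to_numpy()].nunique()
        if obs.any() else 0,
    }
    stats["pct_observable_of_enrolled"] = percent(
        stats["observable_days"], stats["enrolled_days"])
    stats["pct_observable_of_total"] = percent(
        stats["observable_days"], stats["total_days"])
    return stats


def summarize_attrition(
    days: pd.DataFrame, bins: list[TimeBin] | None = None
) -> pd.DataFrame:
    """Stepwise attrition accounting per time bin and overall.

    Day counts partition across bins (each day lies in exactly one bin), so
    bin day counts sum to the ``all`` row; resident and episode counts do not
    sum, since one resident or episode can contribute days to several bins.
    SNF/hospital day counts are tallied among enrolled days and may together
    exceed ``enrolled - observable`` because one day can carry both flags.
    """
    bins = bins or DEFAULT_BINS
    if days.empty:
        return pd.DataFrame(
            {c: [0] * (len(bins) + 1) for c in ATTRITION_COLUMNS},
            index=[b.label for b in bins] + ["all"],
        ).assign(pct_observable_of_enrolled=None, pct_observable_of_total=None)
    if "time_bin" not in days.columns:
        days = assign_time_bins(days, bins)
    # run ids computed on the full observable set so an observable episode
    # spanning several bins is counted once per bin it touches and once overall
    d = days.sort_values(["resident_id", "episode_id", "date"],
                         kind="mergesort").reset_index(drop=True)
    obs_runs_all = observable_run_ids(d[observable_mask(d)])
    runs = pd.Series(np.zeros(len(d), dtype=np.int64), index=d.index)
    runs[observable_mask(d).to_numpy()] = obs_runs_all.to_numpy()
    rows = {}
    for b in bins:
        sub = d[d["time_bin"] == b.label]
        rows[b.label] = _bin_stats(sub, runs.loc[sub.index])
    rows["all"] = _bin_stats(d, runs)
    out = pd.DataFrame.from_dict(rows, orient="index")[ATTRITION_COLUMNS]
    return out


def attrition_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute the percentage columns from the count columns."""
    out = summary.copy()
    out["pct_observable_of_enrolled"] = [
        percent(o, e) for o, e in zip(out["observable_days"], out["enrolled_days"])
    ]
    out["pct_observable_of_total"] = [
        percent(o, t) for o, t in zip(out["observable_days"], out["total_days"])
    ]
    return out


def classify_long_stay_method2(
    days: pd.DataFrame, cutoff: int = 101
) -> pd.DataFrame:
    """Flag episodes reaching the long-stay cutoff (day index >= cutoff).

    Returns one row per NH admission episode with ``long_stay`` and, for
    qualifying episodes, the ``qualifying_date`` (episode start + cutoff - 1
    days).  Observability flags are ignored by construction.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if days.empty:
        return pd.DataFrame(columns=[
            "resident_id", "episode_id", "long_stay", "qualifying_date"])
    grp = days.groupby(["resident_id", "episode_id"], sort=True).agg(
        max_index=("day_index", "max"), start=("date", "min"),
    ).reset_index()
    grp["long_stay"] = (grp["max_index"] >= cutoff).astype(np.int8)
    grp["qualifying_date"] = pd.NaT
    mask = grp["long_stay"] == 1
    grp.loc[mask, "qualifying_date"] = (
        grp.loc[mask, "start"] + pd.Timedelta(days=cutoff - 1)
    )
    return grp[["resident_id", "episode_id", "long_stay", "qualifying_date"]]


def long_stay_days(
    days: pd.DataFrame,
    classifications: pd.DataFrame,
    cutoff: int = 101,
    attribution: str = "from_cutoff",
) -> pd.DataFrame:
    """Person-time attributed to long-stay status.

    ``from_cutoff`` keeps days with ``day_index >= cutoff`` in qualifying
    episodes; ``whole_episode`` keeps every day of a qualifying episode.
    """
    if attribution not in ("from_cutoff", "whole_episode"):
        raise ValueError("attribution must be 'from_cutoff' or 'whole_episode'")
    qualifying = set(
        classifications.loc[classifications["long_stay"] == 1, "episode_id"])
    sub = days[days["episode_id"].isin(qualifying)]
    if attribution == "from_cutoff":
        sub = sub[sub["day_index"] >= cutoff]
    return sub


def compare_algorithms(
    days: pd.DataFrame,
    observable_days: dict[str, pd.DataFrame],
    classifications: pd.DataFrame,
    month: str,
    *,
    cutoff: int = 101,
    attribution: str = "from_cutoff",
) -> pd.DataFrame:
    """Monthly head-to-head of observability algorithms vs the long-stay cutoff.

    ``observable_days`` maps algorithm labels (e.g. ``entry``,
    ``admission_assessment``) to their observable day grids; ``days`` is the
    fully flagged admission-anchored grid on which long-stay person-time and
    its unobservable share are computed.  For each algorithm the comparison
    counts residents with at least one qualifying day in the month and the
    number of qualifying days; for the long-stay row, ``unobservable_share``
    is the fraction of its in-month person-time that is not observable
    medication-use time.
    """
    period = pd.Period(month, freq="M")
    lo, hi = days["date"].min(), days["date"].max()
    if days.empty or period < lo.to_period("M") or period > hi.to_period("M"):
        raise ValueError(f"month {month} lies outside the day grid "
                         f"({lo} .. {hi})")

    def in_month(frame: pd.DataFrame) -> pd.DataFrame:
        return frame[frame["date"].dt.to_period("M") == period]

    rows = []
    for label, obs in observable_days.items():
        sub = in_month(obs)
        rows.append({
            "algorithm": label,
            "n_residents": sub["resident_id"].nunique(),
            "n_days": len(sub),
            "unobservable_share": np.nan,
        })
    ls = in_month(long_stay_days(days, classifications, cutoff, attribution))
    share = (
        float(1.0 - observable_mask(ls).mean()) if len(ls) else np.nan
    )
    rows.append({
        "algorithm": f"long_stay_{cutoff}d",
        "n_residents": ls["resident_id"].nunique(),
        "n_days": len(ls),
        "unobservable_share": share,
    })
    return pd.DataFrame(rows)


def point_prevalence(
    dispensings: pd.DataFrame,
    observable_days: pd.DataFrame,
    month: str,
) -> float:
    """Share of residents observable in the month with drug coverage there.

    Numerator: residents with at least one dispensing whose supply interval
    ``[fill, fill + days_supply - 1]`` intersects one of their observable
    days in the month.  Denominator: residents with at least one observable
    day in the month.  Dispensings with nonpositive days supply are rejected
    with a logged error record.  Returns NaN when the denominator is empty.
    """
    period = pd.Period(month, freq="M")
    obs = observable_days[observable_days["date"].dt.to_period("M") == period]
    denom_ids = set(obs["resident_id"].unique())
    if not denom_ids:
        return float("nan")
    disp = dispensings
    if len(disp):
        bad = disp["days_supply"] <= 0
        if bad.any():
            log.error("rejected %d dispensings with nonpositive days supply",
                      int(bad.sum()))
            disp = disp[~bad]
    if disp.empty:
        return 0.0
    merged = obs.merge(
        disp[["resident_id", "fill_date", "days_supply"]], on="resident_id")
    covered = (
        (merged["date"] >= merged["fill_date"])
        & (merged["date"] <= merged["fill_date"]
           + pd.to_timedelta(merged["days_supply"] - 1, unit="D"))
    )
    numer_ids = set(merged.loc[covered, "resident_id"].unique())
    return len(numer_ids) / len(denom_ids)
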