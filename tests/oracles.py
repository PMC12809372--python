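"""Brute-force per-resident per-day oracles, independent of the library path.

Everything here works by explicit date loops over python sets and dicts: day
sets for interval merging, a triple loop (episode x day x record) for the
flag grid, and a linear scan for observable run-length grouping.  The
library's interval-join implementations are asserted bit-for-bit against
these.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

import pandas as pd

import nhobs

ONE_DAY = pd.Timedelta(days=1)


def small_params(seed: int, **overrides) -> "nhobs.SimParams":
    """A compact one-year scenario used across the suite."""
    base = dict(
        n_residents=10,
        study_start=dt.date(2016, 1, 1),
        study_end=dt.date(2016, 12, 31),
        seed=seed,
    )
    base.update(overrides)
    return nhobs.SimParams(**base)


def daterange(a, b):
    """Closed range of Timestamps."""
    d = a
    while d <= b:
        yield d
        d += ONE_DAY


def interval_day_set(intervals) -> set:
    """Union of days covered by closed [start, end] intervals."""
    out = set()
    for a, b in intervals:
        out.update(daterange(a, b))
    return out


def episode_day_set(episodes: pd.DataFrame) -> set:
    """(resident, day) pairs covered by an episode table."""
    out = set()
    for r in episodes.itertuples():
        for d in daterange(r.start_date, r.end_date):
            out.add((r.resident_id, d))
    return out


def oracle_flag_grid(
    episodes: pd.DataFrame,
    enrollment: pd.DataFrame,
    stays: pd.DataFrame,
    include_discharge_day: bool = False,
) -> dict:
    """Triple-loop day grid: {(rid, episode_id, date): (idx, enr, snf, hosp)}."""
    enr_ok = {}
    for r in enrollment.itertuples():
        ok = (r.part_a == 1 and r.part_b == 1 and r.part_d == 1
              and r.managed_care == 0)
        enr_ok[(r.resident_id, str(r.year_month))] = ok
    stay_rows = list(stays.itertuples())
    grid = {}
    for ep in episodes.itertuples():
        idx = 0
        for d in daterange(ep.start_date, ep.end_date):
            idx += 1
            ym = f"{d.year:04d}-{d.month:02d}"
            enrolled = int(enr_ok.get((ep.resident_id, ym), False))
            snf = hosp = 0
            for s in stay_rows:
                if s.resident_id != ep.resident_id:
                    continue
                if include_discharge_day:
                    inside = s.admit_date <= d <= s.discharge_date
                else:
                    inside = s.admit_date <= d < s.discharge_date
                if inside:
                    if s.stay_type == "snf":
                        snf = 1
                    else:
                        hosp = 1
            grid[(ep.resident_id, ep.episode_id, d)] = (idx, enrolled, snf, hosp)
    return grid


def grid_to_dict(days: pd.DataFrame) -> dict:
    return {
        (r.resident_id, r.episode_id, r.date):
        (int(r.day_index), int(r.enrolled), int(r.snf), int(r.hospital))
        for r in days.itertuples()
    }


def oracle_observable_keys(grid: dict) -> set:
    """Filter the oracle grid by the observability predicate."""
    return {k for k, (_, enr, snf, hosp) in grid.items()
            if enr == 1 and snf == 0 and hosp == 0}


def oracle_observable_runs(obs_keys) -> list:
    """Maximal consecutive-date runs within (resident, episode)."""
    by = defaultdict(list)
    for rid, ep, d in obs_keys:
        by[(rid, ep)].append(d)
    runs = []
    for (rid, ep), ds in by.items():
        ds = sorted(ds)
        start = prev = ds[0]
        for d in ds[1:]:
            if (d - prev) == ONE_DAY:
                prev = d
                continue
            runs.append((rid, ep, start, prev, (prev - start).days + 1))
            start = prev = d
        runs.append((rid, ep, start, prev, (prev - start).days + 1))
    return sorted(runs)


def build_flagged_days(lt, anchor="admission_assessment", **episode_kwargs):
    """Library path end to end: episodes -> day grid with all three flags."""
    eps = nhobs.build_episodes(
        lt.mds, lt.study_end, anchor=anchor, deaths=lt.deaths_map(),
        study_start=lt.study_start, **episode_kwargs,
    )
    days = nhobs.expand_to_days(eps)
    stays = nhobs.impute_part_a_discharge(lt.part_a_stays)
    days = nhobs.flag_days(days, lt.enrollment, stays)
    return eps, days
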