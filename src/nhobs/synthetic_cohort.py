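"""Synthetic linked administrative tables for medication-observability studies.

Real studies of nursing-home (NH) medication use link four resident-level
sources: MDS-style tracking/assessment records, a monthly Medicare enrollment
summary, Part A stay records (post-acute skilled nursing and inpatient
hospital), and Part D dispensing claims.  Those files live under data-use
agreements, so this module generates structurally faithful stand-ins with the
features the observability pipeline must handle: SNF lead-ins capped at 100
covered days, mid-stay hospital interruptions, anticipated-return (code 11)
discharge/reentry pairs, enrollment churn at month granularity, managed-care
months, deaths, and missing Part A discharge dates.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimParams.seed``; identical parameters therefore yield byte-identical
tables.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

log = logging.getLogger(__name__)

MDS_COLUMNS = ["resident_id", "record_kind", "event_date", "disposition_code"]
ENROLLMENT_COLUMNS = [
    "resident_id", "year_month", "part_a", "part_b", "part_d", "managed_care",
]
STAY_COLUMNS = [
    "resident_id", "stay_type", "admit_date", "discharge_date", "length_of_stay",
]
DISPENSING_COLUMNS = ["resident_id", "fill_date", "days_supply", "drug_class"]
DEATH_COLUMNS = ["resident_id", "death_date"]

#: Medicare Part A covers at most 100 days of post-acute skilled nursing care
#: per benefit period; generated SNF durations are clipped to this.
SNF_COVERAGE_CAP_DAYS = 100

_SUPPLY_CHOICES = np.array([7, 14, 30, 90])
_SUPPLY_PROBS = np.array([0.1, 0.1, 0.6, 0.2])


class DistributionSpec(BaseModel):
    """A named day-count distribution with optional zero inflation.

    ``name`` must be one of ``constant`` (params: value), ``lognormal``
    (params: median, sigma), ``uniform_int`` (params: low, high, inclusive),
    ``geometric`` (params: mean) or ``poisson`` (params: mean).  Non-constant
    draws are rounded to whole days and floored at 1; ``p_zero`` is the
    probability of returning 0 instead (used for e.g. episodes with no SNF
    lead-in).
    """

    name: Literal["constant", "lognormal", "uniform_int", "geometric", "poisson"]
    params: dict[str, float] = Field(default_factory=dict)
    p_zero: float = Field(0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_params(self) -> "DistributionSpec":
        required = {
            "constant": {"value"},
            "lognormal": {"median", "sigma"},
            "uniform_int": {"low", "high"},
            "geometric": {"mean"},
            "poisson": {"mean"},
        }[self.name]
        missing = required - set(self.params)
        if missing:
            raise ValueError(
                f"distribution '{self.name}' requires params {sorted(required)}; "
                f"missing {sorted(missing)}"
            )
        # duration parameters must produce positive days
        for key in ("median", "sigma", "mean"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"distribution param '{key}' must be positive")
        if self.name == "uniform_int" and self.params["low"] > self.params["high"]:
            raise ValueError("uniform_int requires low <= high")
        if self.name == "constant" and self.params["value"] < 0:
            raise ValueError("constant value must be nonnegative")
        return self

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` day counts as int64 (>=1 unless zero-inflated/constant 0)."""
        p = self.params
        if self.name == "constant":
            vals = np.full(size, int(round(p["value"])), dtype=np.int64)
        elif self.name == "lognormal":
            vals = rng.lognormal(math.log(p["median"]), p["sigma"], size)
            vals = np.maximum(1, np.rint(vals)).astype(np.int64)
        elif self.name == "uniform_int":
            vals = rng.integers(int(p["low"]), int(p["high"]) + 1, size, dtype=np.int64)
            vals = np.maximum(1, vals)
        elif self.name == "geometric":
            vals = rng.geometric(min(1.0, 1.0 / p["mean"]), size).astype(np.int64)
        else:  # poisson
            vals = np.maximum(1, rng.poisson(p["mean"], size)).astype(np.int64)
        if self.p_zero > 0:
            vals = np.where(rng.random(size) < self.p_zero, 0, vals)
        return vals

    def sample_one(self, rng: np.random.Generator) -> int:
        return int(self.sample(rng, 1)[0])


class SimParams(BaseModel):
    """Scenario parameters for :func:`generate_cohort`.

    Defaults echo the study conditions of the national NH cohort this package
    emulates: an eight-year window, ~1.5 admissions per resident, NH lengths
    of stay with median ~31 days and a heavy right tail, SNF lead-ins capped
    at 100 days, and occasional missing Part A discharge dates.
    """

    n_residents: int = Field(100, ge=0)
    study_start: dt.date = dt.date(2013, 1, 1)
    study_end: dt.date = dt.date(2020, 12, 31)
    #: expected NH admissions per resident over the study (Poisson, min 1)
    admission_rate: float = Field(1.5, gt=0)
    los_distribution: DistributionSpec = DistributionSpec(
        name="lognormal", params={"median": 31, "sigma": 0.9}
    )
    #: SNF-covered days at episode start, clipped to [0, 100]; p_zero is the
    #: share of admissions arriving without post-acute coverage
    snf_leadin_distribution: DistributionSpec = DistributionSpec(
        name="lognormal", params={"median": 20, "sigma": 0.6}, p_zero=0.4
    )
    #: expected inpatient hospitalizations per episode-year
    hosp_rate: float = Field(1.0, ge=0)
    hosp_length_distribution: DistributionSpec = DistributionSpec(
        name="lognormal", params={"median": 5, "sigma": 0.5}
    )
    #: probability an admission contains a code-11 discharge/reentry attempt
    reentry_prob: float = Field(0.15, ge=0, le=1)
    #: out-of-facility gap before return; >30 days forces a new admission
    reentry_gap_distribution: DistributionSpec = DistributionSpec(
        name="uniform_int", params={"low": 1, "high": 45}
    )
    #: per resident-month probability of an A/B/D coverage gap
    enrollment_gap_prob: float = Field(0.05, ge=0, le=1)
    #: per resident-month probability of a managed-care (Medicare Advantage) flag
    managed_care_prob: float = Field(0.15, ge=0, le=1)
    #: probability the resident's record ends in death (0-30 days after the
    #: final discharge, or inside an open episode)
    death_prob: float = Field(0.25, ge=0, le=1)
    #: fraction of Part A stay rows with the discharge date blanked
    missing_discharge_frac: float = Field(0.02, ge=0, le=1)
    #: expected dispensings per 30 NH days
    dispensing_rate: float = Field(0.6, ge=0)
    #: share of dispensings labelled gabapentin (the comparator drug class)
    gabapentin_share: float = Field(0.2, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_window(self) -> "SimParams":
        if self.study_start > self.study_end:
            raise ValueError("study_start must be on or before study_end")
        return self


@dataclass
class LinkedTables:
    """The four linked input tables plus the death table and study window."""

    mds: pd.DataFrame
    enrollment: pd.DataFrame
    part_a_stays: pd.DataFrame
    dispensings: pd.DataFrame
    deaths: pd.DataFrame
    study_start: dt.date
    study_end: dt.date

    def deaths_map(self) -> dict[str, pd.Timestamp]:
        return dict(zip(self.deaths["resident_id"], self.deaths["death_date"]))

    def equals(self, other: "LinkedTables") -> bool:
        return (
            self.study_start == other.study_start
            and self.study_end == other.study_end
            and all(
                getattr(self, name).equals(getattr(other, name))
                for name in ("mds", "enrollment", "part_a_stays", "dispensings", "deaths")
            )
        )

    def checksum(self) -> str:
        """SHA-256 over the canonical CSV serialization of all tables."""
        h = hashlib.sha256()
        for name in ("mds", "enrollment", "part_a_stays", "dispensings", "deaths"):
            h.update(getattr(self, name).to_csv(index=False).encode())
        return h.hexdigest()

    def write(self, directory: str | Path, fmt: str = "csv") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("mds", "enrollment", "part_a_stays", "dispensings", "deaths"):
            frame = getattr(self, name)
            if fmt == "csv":
                frame.to_csv(directory / f"{name}.csv", index=False, date_format="%Y-%m-%d")
            elif fmt == "parquet":
                frame.to_parquet(directory / f"{name}.parquet", index=False)
            else:
                raise ValueError(f"unknown format '{fmt}' (expected csv or parquet)")
        meta = {"study_start": self.study_start.isoformat(),
                "study_end": self.study_end.isoformat()}
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def _empty_tables(study_start: dt.date, study_end: dt.date) -> LinkedTables:
    def frame(cols: list[str], date_cols: tuple[str, ...]) -> pd.DataFrame:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in date_cols:
            df[c] = pd.Series(dtype="datetime64[ns]")
        return df

    return LinkedTables(
        mds=frame(MDS_COLUMNS, ("event_date",)),
        enrollment=frame(ENROLLMENT_COLUMNS, ()),
        part_a_stays=frame(STAY_COLUMNS, ("admit_date", "discharge_date")),
        dispensings=frame(DISPENSING_COLUMNS, ("fill_date",)),
        deaths=frame(DEATH_COLUMNS, ("death_date",)),
        study_start=study_start,
        study_end=study_end,
    )


def generate_cohort(params: SimParams) -> LinkedTables:
    """Simulate the four linked tables under ``params``.

    Every generated NH admission carries an entry record and an admission
    assessment dated on/after entry; unless the episode is open at study end
    or ends via an unbridged code-11 discharge, a terminal discharge record
    with disposition 10 or 12 is emitted.  Code-11 discharges whose drawn
    reentry gap is <=30 days are followed by a reentry (entry) record inside
    the same admission; gaps >30 days start a brand-new admission (entry +
    admission assessment), mirroring CMS reentry guidance.
    """
    if params.n_residents == 0:
        return _empty_tables(params.study_start, params.study_end)

    rng = np.random.default_rng(params.seed)
    W = (params.study_end - params.study_start).days + 1  # window length, days
    origin = pd.Timestamp(params.study_start)

    mds_rows: list[tuple[str, str, int, float]] = []   # rid, kind, day, code
    stay_rows: list[tuple[str, str, int, int, int]] = []  # rid, type, admit, disch, los
    disp_rows: list[tuple[str, int, int, str]] = []
    death_rows: list[tuple[str, int]] = []
    enroll_parts: list[pd.DataFrame] = []

    all_months = pd.period_range(params.study_start, params.study_end, freq="M")
    month_starts = np.array(
        [(m.start_time.date() - params.study_start).days for m in all_months]
    )

    for i in range(params.n_residents):
        rid = f"R{i:05d}"
        n_adm = max(1, int(rng.poisson(params.admission_rate)))
        t = int(rng.integers(0, W))
        admissions: list[tuple[int, int, bool]] = []  # (entry, end, open)
        r_mds: list[tuple[str, str, int, float]] = []
        r_stays: list[tuple[str, str, int, int]] = []  # rid, type, admit, disch
        r_disp: list[tuple[str, int, int, str]] = []
        pending = n_adm
        while pending > 0 and t <= W - 1:
            pending -= 1
            entry = t
            los = params.los_distribution.sample_one(rng)
            aa_off = min(int(rng.integers(0, 8)), los - 1)
            r_mds.append((rid, "entry", entry, np.nan))
            r_mds.append((rid, "admission_assessment", entry + aa_off, np.nan))
            final_code = int(rng.choice([10, 12]))

            end = entry + los - 1
            terminal = True  # admission ends with a code-10/12 discharge record
            new_admission_at: int | None = None
            if (
                params.reentry_prob > 0
                and los >= 12
                and rng.random() < params.reentry_prob
            ):
                cut = entry + int(rng.integers(aa_off + 1, los - 3))
                gap = max(1, params.reentry_gap_distribution.sample_one(rng))
                if cut <= W - 1:
                    r_mds.append((rid, "discharge", cut, 11.0))
                    reentry_day = cut + gap
                    if gap <= 30:
                        if reentry_day <= W - 1:
                            r_mds.append((rid, "entry", reentry_day, np.nan))
                            remaining = los - (cut - entry + 1)
                            end = reentry_day + max(1, remaining) - 1
                        else:
                            end = cut  # return fell beyond the study window
                            terminal = False
                    else:
                        # window expired: this admission ends at the code-11
                        # discharge; the return starts a brand-new admission
                        end = cut
                        terminal = False
                        new_admission_at = reentry_day

            is_open = end > W - 1
            if is_open:
                end = W - 1
                terminal = False
            if terminal:
                r_mds.append((rid, "discharge", end, float(final_code)))
            admissions.append((entry, end, is_open))

            # stays: SNF lead-in at entry, hospitalizations, post-hospital SNF
            k = int(np.clip(params.snf_leadin_distribution.sample_one(rng), 0,
                            SNF_COVERAGE_CAP_DAYS))
            if k > 0:
                r_stays.append((rid, "snf", entry, min(entry + k, W)))
            span = end - entry + 1
            if params.hosp_rate > 0:
                n_h = int(rng.poisson(params.hosp_rate * span / 365.0))
                for _ in range(n_h):
                    s = entry + int(rng.integers(0, span))
                    hl = params.hosp_length_distribution.sample_one(rng)
                    d = min(s + hl, W)
                    r_stays.append((rid, "inpatient", s, d))
                    if rng.random() < 0.5:
                        ks = int(np.clip(
                            params.snf_leadin_distribution.sample_one(rng), 0,
                            SNF_COVERAGE_CAP_DAYS))
                        if ks > 0 and d <= W - 1:
                            r_stays.append((rid, "snf", d, min(d + ks, W)))

            # dispensings within the admission
            if params.dispensing_rate > 0:
                n_f = int(rng.poisson(params.dispensing_rate * span / 30.0))
                for _ in range(n_f):
                    fill = entry + int(rng.integers(0, span))
                    supply = int(rng.choice(_SUPPLY_CHOICES, p=_SUPPLY_PROBS))
                    drug = ("gabapentin" if rng.random() < params.gabapentin_share
                            else "other")
                    r_disp.append((rid, fill, supply, drug))

            if new_admission_at is not None and new_admission_at <= W - 1:
                t = new_admission_at
            else:
                t = end + 2 + int(rng.exponential(60.0))

        # death
        death_day: int | None = None
        if admissions and rng.random() < params.death_prob:
            entry_l, end_l, open_l = admissions[-1]
            if open_l:
                death_day = int(rng.integers(entry_l, W))
            else:
                death_day = min(end_l + int(rng.integers(0, 31)), W - 1)
            death_rows.append((rid, death_day))

        # enrollment months through death (or study end)
        last_day = W - 1 if death_day is None else death_day
        n_months = int(np.searchsorted(month_starts, last_day, side="right"))
        k_m = max(1, n_months)
        gap = rng.random(k_m) < params.enrollment_gap_prob
        drop_ab = rng.random(k_m) < 0.5
        mc = (rng.random(k_m) < params.managed_care_prob).astype(np.int8)
        part_d = np.where(gap, 0, 1).astype(np.int8)
        part_ab = np.where(gap & drop_ab, 0, 1).astype(np.int8)
        enroll_parts.append(pd.DataFrame({
            "resident_id": rid,
            "year_month": all_months[:k_m].astype(str),
            "part_a": part_ab, "part_b": part_ab,
            "part_d": part_d, "managed_care": mc,
        }))

        # no claims activity after death; stays truncated at the day after death
        if death_day is not None:
            r_stays = [
                (r, ty, a, min(d, death_day + 1))
                for (r, ty, a, d) in r_stays if a <= death_day
            ]
            r_disp = [(r, f, s, dr) for (r, f, s, dr) in r_disp if f <= death_day]
        mds_rows.extend(r_mds)
        stay_rows.extend((r, ty, a, d, d - a) for (r, ty, a, d) in r_stays)
        disp_rows.extend(r_disp)

    mds = pd.DataFrame(mds_rows, columns=MDS_COLUMNS)
    mds["event_date"] = origin + pd.to_timedelta(mds["event_date"].astype(int), unit="D")
    mds = mds.sort_values(["resident_id", "event_date", "record_kind"],
                          kind="mergesort").reset_index(drop=True)

    enrollment = (
        pd.concat(enroll_parts, ignore_index=True)
        if enroll_parts else _empty_tables(params.study_start, params.study_end).enrollment
    )

    stays = pd.DataFrame(stay_rows, columns=STAY_COLUMNS)
    if len(stays):
        stays["admit_date"] = origin + pd.to_timedelta(stays["admit_date"].astype(int), unit="D")
        stays["discharge_date"] = origin + pd.to_timedelta(
            stays["discharge_date"].astype(int), unit="D")
        stays = stays.sort_values(["resident_id", "admit_date", "stay_type"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        stays = _empty_tables(params.study_start, params.study_end).part_a_stays

    if params.missing_discharge_frac > 0 and len(stays):
        stays = inject_missing_discharges(
            stays, params.missing_discharge_frac,
            seed=int(rng.integers(2**31)))

    disp = pd.DataFrame(disp_rows, columns=DISPENSING_COLUMNS)
    if len(disp):
        disp["fill_date"] = origin + pd.to_timedelta(disp["fill_date"].astype(int), unit="D")
        disp = disp.sort_values(["resident_id", "fill_date", "drug_class"],
                                kind="mergesort").reset_index(drop=True)
    else:
        disp = _empty_tables(params.study_start, params.study_end).dispensings

    deaths = pd.DataFrame(death_rows, columns=DEATH_COLUMNS)
    if len(deaths):
        deaths["death_date"] = origin + pd.to_timedelta(deaths["death_date"].astype(int), unit="D")
    else:
        deaths = _empty_tables(params.study_start, params.study_end).deaths

    return LinkedTables(
        mds=mds, enrollment=enrollment, part_a_stays=stays,
        dispensings=disp, deaths=deaths,
        study_start=params.study_start, study_end=params.study_end,
    )


def inject_missing_discharges(
    stays: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Blank the discharge date on exactly ``round(fraction * n)`` stay rows.

    The length-of-stay field is retained, so downstream imputation
    (``discharge = admit + length_of_stay``) restores the original dates
    exactly.  Row order is preserved.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    stays = stays.copy()
    n = len(stays)
    n_blank = int(n * fraction + 0.5)
    if n_blank == 0:
        return stays
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_blank, replace=False)
    col = stays.columns.get_loc("discharge_date")
    stays.iloc[idx, col] = pd.NaT
    log.info("blanked %d of %d Part A discharge dates", n_blank, n)
    return stays
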