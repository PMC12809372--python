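"""Table schemas, readers/writers, and input validation.

All tables move as CSV (ISO-8601 dates) or Parquet.  ``validate_tables``
returns a violation report rather than raising: column presence, date
parsability, indicator and disposition-code domains (A0310F must be 10, 11
or 12 and appear only on discharge records), duplicate resident-month keys,
stay-interval sanity, and referential integrity of resident ids against the
MDS table.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import pandas as pd

from .synthetic_cohort import (
    DEATH_COLUMNS,
    DISPENSING_COLUMNS,
    ENROLLMENT_COLUMNS,
    MDS_COLUMNS,
    STAY_COLUMNS,
    LinkedTables,
)

TABLE_SCHEMAS: dict[str, dict[str, list[str]]] = {
    "mds": {"columns": MDS_COLUMNS, "dates": ["event_date"]},
    "enrollment": {"columns": ENROLLMENT_COLUMNS, "dates": []},
    "part_a_stays": {"columns": STAY_COLUMNS,
                     "dates": ["admit_date", "discharge_date"]},
    "dispensings": {"columns": DISPENSING_COLUMNS, "dates": ["fill_date"]},
    "deaths": {"columns": DEATH_COLUMNS, "dates": ["death_date"]},
}

RECORD_KINDS = {"entry", "discharge", "admission_assessment", "other_assessment"}
DISPOSITION_CODES = {10, 11, 12}
STAY_TYPES = {"snf", "inpatient"}


def read_tables(directory: str | Path, fmt: str = "csv") -> LinkedTables:
    """Load the five tables (and meta.json study window) from a directory."""
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, schema in TABLE_SCHEMAS.items():
        path = directory / f"{name}.{'csv' if fmt == 'csv' else 'parquet'}"
        if fmt == "csv":
            df = pd.read_csv(path)
        else:
            df = pd.read_parquet(path)
        for col in schema["dates"]:
            df[col] = pd.to_datetime(df[col], errors="coerce")
        frames[name] = df
    meta_path = directory / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        start = dt.date.fromisoformat(meta["study_start"])
        end = dt.date.fromisoformat(meta["study_end"])
    else:  # fall back to the observed span of the MDS records
        start = frames["mds"]["event_date"].min().date()
        end = frames["mds"]["event_date"].max().date()
    return LinkedTables(
        mds=frames["mds"], enrollment=frames["enrollment"],
        part_a_stays=frames["part_a_stays"], dispensings=frames["dispensings"],
        deaths=frames["deaths"], study_start=start, study_end=end,
    )


def _violations(table: str, rows, column: str, message: str) -> list[dict]:
    return [{"table": table, "row": int(r), "column": column, "message": message}
            for r in rows]


def validate_tables(tables: LinkedTables) -> pd.DataFrame:
    """Check schemas and domains; the report (not an exception) is the product.

    Returns a DataFrame with columns ``table, row, column, message``; an
    empty frame means the inputs pass.  Date columns may arrive as strings
    (the CSV path); unparsable values are reported with their row numbers.
    """
    out: list[dict] = []
    frames = {name: getattr(tables, name) for name in TABLE_SCHEMAS}
    parsed: dict[str, pd.DataFrame] = {}
    for name, schema in TABLE_SCHEMAS.items():
        df = frames[name]
        missing = [c for c in schema["columns"] if c not in df.columns]
        for c in missing:
            out.append({"table": name, "row": -1, "column": c,
                        "message": "required column missing"})
        if missing:
            continue
        df = df.copy()
        for col in schema["dates"]:
            raw = df[col]
            coerced = pd.to_datetime(raw, errors="coerce")
            bad = coerced.isna() & raw.notna()
            out += _violations(name, df.index[bad], col, "unparsable date")
            df[col] = coerced
        parsed[name] = df

    if "mds" in parsed:
        mds = parsed["mds"]
        bad_kind = ~mds["record_kind"].isin(RECORD_KINDS)
        out += _violations("mds", mds.index[bad_kind], "record_kind",
                           "unknown record kind")
        is_discharge = mds["record_kind"] == "discharge"
        code = mds["disposition_code"]
        bad_code = is_discharge & ~code.isin(DISPOSITION_CODES)
        out += _violations(
            "mds", mds.index[bad_code], "disposition_code",
            "A0310F disposition code must be 10, 11, or 12 on discharge records")
        stray = ~is_discharge & code.notna()
        out += _violations(
            "mds", mds.index[stray], "disposition_code",
            "disposition code present on non-discharge record")

    if "enrollment" in parsed:
        enr = parsed["enrollment"]
        dup = enr.duplicated(["resident_id", "year_month"], keep=False)
        out += _violations("enrollment", enr.index[dup & enr.duplicated(
            ["resident_id", "year_month"])], "year_month",
            "duplicate resident-month row")
        for col in ("part_a", "part_b", "part_d", "managed_care"):
            bad = ~enr[col].isin([0, 1])
            out += _violations("enrollment", enr.index[bad], col,
                               "indicator must be 0 or 1")
        bad_month = pd.to_datetime(
            enr["year_month"].astype(str), format="%Y-%m", errors="coerce"
        ).isna()
        out += _violations("enrollment", enr.index[bad_month], "year_month",
                           "unparsable year-month (expected YYYY-MM)")

    if "part_a_stays" in parsed:
        st = parsed["part_a_stays"]
        bad_type = ~st["stay_type"].isin(STAY_TYPES)
        out += _violations("part_a_stays", st.index[bad_type], "stay_type",
                           "stay_type must be snf or inpatient")
        both = st["discharge_date"].notna()
        bad_order = both & (st["discharge_date"] < st["admit_date"])
        out += _violations("part_a_stays", st.index[bad_order], "discharge_date",
                           "discharge date precedes admission date")
        neither = st["discharge_date"].isna() & st["length_of_stay"].isna()
        out += _violations("part_a_stays", st.index[neither], "length_of_stay",
                           "missing both discharge date and length of stay")

    if "dispensings" in parsed:
        disp = parsed["dispensings"]
        if len(disp):
            bad = ~(disp["days_supply"] > 0)
            out += _violations("dispensings", disp.index[bad], "days_supply",
                               "days supply must be positive")

    if "mds" in parsed:
        known = set(parsed["mds"]["resident_id"])
        for name in ("enrollment", "part_a_stays", "dispensings", "deaths"):
            if name not in parsed:
                continue
            df = parsed[name]
            if not len(df):
                continue
            bad = ~df["resident_id"].isin(known)
            out += _violations(name, df.index[bad], "resident_id",
                               "resident id absent from MDS table")

    report = pd.DataFrame(out, columns=["table", "row", "column", "message"])
    return report


def write_tables(tables: LinkedTables, directory: str | Path,
                 fmt: str = "csv") -> None:
    tables.write(directory, fmt)
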