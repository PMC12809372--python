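"""End-to-end pipeline: inputs -> episodes -> flagged days -> observable time.

Large day grids are processed in resident partitions: residents are assigned
to ``n_partitions`` buckets by a stable MD5 hash of the resident id (never by
date, so every algorithm step stays per-resident and embarrassingly
parallel), each partition runs the episode/flag/observable steps
independently, and the partition outputs are appended and canonically
sorted.  The final tables are invariant to ``n_partitions`` — that
invariance is the testable contract of the partitioned-execution design.

A :class:`RunManifest` records the config echo, per-step row counts and
removal counts, per-partition sizes, output checksums, and wall-clock per
step, giving an auditable attrition trail.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort_summaries import (
    attrition_percentages,
    classify_long_stay_method2,
    compare_algorithms,
    point_prevalence,
    summarize_attrition,
)
from .day_classifier import (
    FLAG_COLUMNS,
    expand_to_days,
    flag_days,
    impute_part_a_discharge,
)
from .episode_builder import build_episodes
from .io import read_tables, validate_tables
from .observable_time import (
    assign_time_bins,
    build_observable_episodes,
    select_observable_days,
)
from .synthetic_cohort import LinkedTables, SimParams, generate_cohort

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Full configuration for one pipeline run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    #: directory containing the input tables (exclusive with ``simulate``)
    tables_dir: Optional[Path] = None
    #: generate inputs instead of reading them
    simulate: Optional[SimParams] = None
    format: Literal["csv", "parquet"] = "csv"
    study_start: Optional[dt.date] = None
    study_end: Optional[dt.date] = None
    anchor: Literal["entry", "admission_assessment"] = "admission_assessment"
    admission_day_one: Literal["entry", "assessment"] = "entry"
    count_discharge_day: bool = True
    drop_out_of_facility_gaps: bool = False
    include_discharge_day: bool = False
    enrollment_granularity: Literal["month", "day"] = "month"
    long_stay_cutoff: int = Field(101, ge=1)
    long_stay_attribution: Literal["from_cutoff", "whole_episode"] = "from_cutoff"
    n_partitions: int = Field(1, ge=1)
    output_dir: Optional[Path] = None
    write_day_grid: bool = False
    #: month (YYYY-MM) for the algorithm comparison and drug prevalence
    compare_month: Optional[str] = None
    #: drug class used for the point-prevalence comparator
    drug_class: Optional[str] = "gabapentin"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


class PipelineValidationError(RuntimeError):
    """Raised when input tables fail schema validation; carries the report."""

    def __init__(self, report: pd.DataFrame):
        super().__init__(f"{len(report)} schema violations in input tables")
        self.report = report


@dataclass
class PipelineResult:
    episodes: pd.DataFrame
    day_grid: pd.DataFrame
    observable_days: pd.DataFrame
    observable_episodes: pd.DataFrame
    attrition: pd.DataFrame
    comparison: Optional[pd.DataFrame]
    prevalence: Optional[float]
    manifest: dict = field(default_factory=dict)


def partition_of(resident_id: str, n_partitions: int) -> int:
    """Stable partition assignment by MD5 hash of the resident id."""
    digest = hashlib.md5(str(resident_id).encode()).hexdigest()
    return int(digest, 16) % n_partitions


def _checksum(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False, date_format="%Y-%m-%d").encode()
    ).hexdigest()


def _canonical(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    return frame.sort_values(keys, kind="mergesort").reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full algorithm under ``config`` and return all outputs.

    Steps: load or simulate the linked tables; validate (violations abort the
    run); impute missing Part A discharge dates; per resident-partition,
    build episodes for the configured anchor, expand to days, set the three
    flags, and extract observable days; append partitions; summarize
    attrition; optionally run the monthly algorithm comparison and drug
    point prevalence.  Writes CSV/Parquet outputs plus ``manifest.json`` when
    ``output_dir`` is set.
    """
    t0 = time.perf_counter()
    manifest: dict = {"version": __version__,
                      "config": json.loads(config.model_dump_json()),
                      "steps": {}, "timings_s": {}}

    if (config.tables_dir is None) == (config.simulate is None):
        raise ValueError("config must set exactly one of tables_dir or simulate")
    if config.simulate is not None:
        tables = generate_cohort(config.simulate)
    else:
        tables = read_tables(config.tables_dir, config.format)
    study_start = config.study_start or tables.study_start
    study_end = config.study_end or tables.study_end
    manifest["steps"]["load"] = {
        "mds_rows": len(tables.mds), "enrollment_rows": len(tables.enrollment),
        "stay_rows": len(tables.part_a_stays),
        "dispensing_rows": len(tables.dispensings),
        "death_rows": len(tables.deaths),
    }
    manifest["timings_s"]["load"] = round(time.perf_counter() - t0, 3)

    report = validate_tables(tables)
    if len(report):
        raise PipelineValidationError(report)

    t1 = time.perf_counter()
    stays = impute_part_a_discharge(tables.part_a_stays)
    manifest["steps"]["impute"] = {
        "imputed": int(tables.part_a_stays["discharge_date"].isna().sum()),
        "rejected": len(tables.part_a_stays) - len(stays),
    }

    deaths = tables.deaths_map()
    n_parts = config.n_partitions
    parts = {
        rid: partition_of(rid, n_parts)
        for rid in tables.mds["resident_id"].unique()
    }
    part_series = tables.mds["resident_id"].map(parts)

    episodes_parts, days_parts = [], []
    partition_sizes = {}
    for p in range(n_parts):
        mds_p = tables.mds[part_series == p]
        if mds_p.empty:
            partition_sizes[p] = 0
            continue
        rids = set(mds_p["resident_id"])
        eps = build_episodes(
            mds_p, study_end,
            anchor=config.anchor,
            deaths={r: d for r, d in deaths.items() if r in rids},
            study_start=study_start,
            admission_day_one=config.admission_day_one,
            count_discharge_day=config.count_discharge_day,
            drop_out_of_facility_gaps=config.drop_out_of_facility_gaps,
        )
        days = expand_to_days(eps)
        days = flag_days(
            days,
            tables.enrollment[tables.enrollment["resident_id"].isin(rids)],
            stays[stays["resident_id"].isin(rids)],
            enrollment_granularity=config.enrollment_granularity,
            include_discharge_day=config.include_discharge_day,
        )
        episodes_parts.append(eps)
        days_parts.append(days)
        partition_sizes[p] = len(rids)
    manifest["steps"]["partitions"] = partition_sizes

    episodes = _canonical(
        pd.concat(episodes_parts, ignore_index=True)
        if episodes_parts else build_episodes(tables.mds, study_end),
        ["resident_id", "start_date"],
    )
    day_grid = _canonical(
        pd.concat(days_parts, ignore_index=True)
        if days_parts else expand_to_days(episodes),
        ["resident_id", "episode_id", "date"],
    )
    for c in FLAG_COLUMNS:  # empty grids never saw the flagging steps
        if c not in day_grid.columns:
            day_grid[c] = pd.Series(dtype="int8")
    day_grid = assign_time_bins(day_grid)
    manifest["steps"]["episodes"] = {
        "n_episodes": len(episodes),
        "by_end_reason": episodes["end_reason"].value_counts().to_dict()
        if len(episodes) else {},
    }
    manifest["timings_s"]["episodes_and_days"] = round(
        time.perf_counter() - t1, 3)

    t2 = time.perf_counter()
    observable = select_observable_days(day_grid)
    obs_episodes = build_observable_episodes(observable)
    attrition = attrition_percentages(summarize_attrition(day_grid))
    enrolled = int((day_grid["enrolled"] == 1).sum()) if len(day_grid) else 0
    manifest["steps"]["observable"] = {
        "total_days": len(day_grid),
        "unenrolled_days": len(day_grid) - enrolled,
        "enrolled_snf_days": int(attrition.loc["all", "snf_days"]),
        "enrolled_hospital_days": int(attrition.loc["all", "hospital_days"]),
        "observable_days": len(observable),
        "unique_removed_days": len(day_grid) - len(observable),
        "n_observable_episodes": len(obs_episodes),
    }
    manifest["timings_s"]["observable"] = round(time.perf_counter() - t2, 3)

    comparison = None
    prevalence = None
    if config.compare_month:
        entry_eps = build_episodes(
            tables.mds, study_end, anchor="entry",
            deaths=deaths, study_start=study_start,
            count_discharge_day=config.count_discharge_day,
        )
        entry_days = flag_days(
            expand_to_days(entry_eps), tables.enrollment, stays,
            enrollment_granularity=config.enrollment_granularity,
            include_discharge_day=config.include_discharge_day,
        )
        entry_obs = select_observable_days(entry_days)
        admission_obs = (
            observable if config.anchor == "admission_assessment"
            else select_observable_days(day_grid)
        )
        classifications = classify_long_stay_method2(
            day_grid, config.long_stay_cutoff)
        comparison = compare_algorithms(
            day_grid,
            {"entry": entry_obs, "admission_assessment": admission_obs},
            classifications, config.compare_month,
            cutoff=config.long_stay_cutoff,
            attribution=config.long_stay_attribution,
        )
        disp = tables.dispensings
        if config.drug_class and len(disp):
            disp = disp[disp["drug_class"] == config.drug_class]
        if len(observable):
            prevalence = point_prevalence(disp, observable, config.compare_month)

    manifest["checksums"] = {
        "episodes": _checksum(episodes),
        "day_grid": _checksum(day_grid),
        "observable_episodes": _checksum(obs_episodes),
        "attrition": _checksum(attrition.reset_index(names="bin")),
    }
    manifest["timings_s"]["total"] = round(time.perf_counter() - t0, 3)

    result = PipelineResult(
        episodes=episodes, day_grid=day_grid, observable_days=observable,
        observable_episodes=obs_episodes, attrition=attrition,
        comparison=comparison, prevalence=prevalence, manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write(frame: pd.DataFrame, name: str) -> None:
        if config.format == "parquet":
            frame.to_parquet(out / f"{name}.parquet", index=False)
        else:
            frame.to_csv(out / f"{name}.csv", index=False,
                         date_format="%Y-%m-%d")

    write(result.episodes, "episodes")
    write(result.observable_episodes, "observable_episodes")
    write(result.attrition.reset_index(names="bin"), "attrition")
    if config.write_day_grid:
        write(result.day_grid, "day_grid")
    if result.comparison is not None:
        write(result.comparison, "comparison")
    if result.prevalence is not None:
        (out / "prevalence.json").write_text(json.dumps(
            {"month": config.compare_month, "drug_class": config.drug_class,
             "point_prevalence": result.prevalence}, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  default=str))
    log.info("wrote pipeline outputs to %s", out)
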