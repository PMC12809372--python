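# nhobs — observable medication-use time in nursing-home claims

Medications dispensed to US nursing-home (NH) residents are visible in
Medicare Part D claims only some of the time: during Part A post-acute
skilled-nursing (SNF) coverage and inpatient hospitalizations, dispensings
are bundled into facility payments and never appear as claims, and nothing
is observable for residents without Parts A+B+D fee-for-service enrollment.
Studies that ignore this suffer *immeasurable-time bias*; the traditional
workaround — restricting to "long-stay" residents past day 100 of their
admission — discards real observable person-time and still keeps
unobservable days.

`nhobs` implements a person-day–level alternative for pharmacoepidemiologists
working with linked MDS/MedPAR/enrollment-style data:

1. **Episodes** — build NH episodes from MDS-style tracking records, either
   *entry-anchored* (entry record → next discharge) or
   *admission-assessment-anchored* (episodes end at an A0310F = 10/12
   discharge, or at an A0310F = 11 discharge with no reentry within 30 days;
   a reentry ≤ 30 days later continues the episode). Overlapping episodes
   merge (first entry to last discharge), open episodes close at study end,
   and all episodes truncate at death.
2. **Day grid** — expand episodes to one row per resident-day (day 1 = the
   admission date) and flag each day: `enrolled` (Parts A+B+D, no managed
   care, judged by calendar month), `snf` and `hospital` (Part A stays under
   the half-open `[admit, discharge)` convention, with missing discharge
   dates imputed as `admit + length_of_stay`).
3. **Observable time** — keep days with `enrolled=1 ∧ snf=0 ∧ hospital=0`
   and store maximal runs of consecutive observable days as *observable
   episodes*, the usable person-time denominator.
4. **Reporting** — stepwise attrition tables by time-since-admission bins
   (days 1–30 / 31–60 / 61–100 / 101+), a configurable 101-day long-stay
   comparator, monthly algorithm comparisons, and drug point prevalence
   within observable time.

Because real Medicare data live under data-use agreements, the package ships
a synthetic-cohort generator (`SimParams` / `generate_cohort`) that emulates
all four linked input tables — with SNF lead-ins capped at 100 covered days,
mid-stay hospitalizations, code-11 discharge/reentry pairs, monthly
enrollment churn, deaths, and missing discharge dates — plus a catalog of
hand-auditable fixtures (`make_fixture`).

## Worked example

```python
import nhobs

lt = nhobs.make_fixture("figure1_schematic")   # one resident, 122-day stay
eps = nhobs.build_episodes(lt.mds, lt.study_end, deaths=lt.deaths_map())
days = nhobs.flag_days(nhobs.expand_to_days(eps), lt.enrollment,
                       nhobs.impute_part_a_discharge(lt.part_a_stays))
obs = nhobs.select_observable_days(days)
print(nhobs.build_observable_episodes(obs))
```

```
  resident_id episode_id obs_episode_id start_date   end_date  n_days
0          F1     F1:001      F1:001:01 2016-03-21 2016-05-09      50
1          F1     F1:001      F1:001:02 2016-05-15 2016-06-30      47
```

The 122-day stay starts with 20 SNF-covered days and contains a 5-day May
hospitalization, so 97 days remain observable, split into two runs around
the hospitalization. `examples/` contains this walkthrough plus narrative
scripts for cohort-level attrition and the long-stay comparison.

A thin CLI mirrors the pipeline stages:

```bash
nhobs simulate --out tables/ --n-residents 300 --seed 42
nhobs run --config config.yaml      # end to end, writes attrition + manifest
```

Large cohorts are processed in resident-hash partitions
(`n_partitions` in the config); outputs are provably invariant to the
partition count.

## Scope

The package handles tabular MDS-like inputs (CSV/Parquet), not raw MDS 3.0
fixed-width files; it does not model Part A benefit exhaustion, Medicare
Advantage encounter data, or drug–outcome associations. See
`docs/methods.md` for conventions, parameter defaults, and limitations.
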