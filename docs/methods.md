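# Methods

## Problem and model

Part D dispensing claims for US nursing-home (NH) residents exist only on
days when (a) the resident is enrolled in Medicare Parts A, B and D without
managed care, (b) the day is not covered by a bundled Part A post-acute
skilled-nursing (SNF) payment, and (c) the resident is not hospitalized.
`nhobs` classifies every NH person-day against these three conditions and
rebuilds the surviving days into contiguous *observable medication-use
episodes*. The unit of analysis is the resident-day; episodes exist only as
intervals over days, so every rule below reduces to set operations on days.

## Episode construction

**Record model.** Input MDS-like records carry a resident id, a record kind
(`entry`, `discharge`, `admission_assessment`, `other_assessment`), an event
date, and — on discharges only — an A0310F disposition code (10/12 = return
not anticipated, 11 = return anticipated). Records on the same date sort
entry → assessment → discharge, so a same-day entry/discharge pair is a
one-day episode.

**Entry anchoring.** Each entry record pairs with the first *unconsumed*
discharge on or after it. This keeps interleaved entry/discharge pairs
distinct (two overlapping pairs merge to first-entry/last-discharge in the
merge step rather than collapsing onto the earlier discharge); when every
later discharge is already consumed — two entries sharing one discharge —
the entry reuses the earliest discharge on/after it, and an entry with no
later discharge stays open until study end.

**Admission anchoring.** An episode needs an admission assessment; its day 1
is the nearest entry record on/before the assessment (falling back to the
assessment date; a config switch anchors day 1 on the assessment itself,
since source data do not always make the intent unambiguous). Scanning
forward: codes 10/12 end the episode; a code-11 discharge ends it only if no
reentry (entry record) follows within 30 days, measured as
`(reentry − discharge) ≤ 30` with the boundary inclusive. Later admission
assessments inside a continuing episode are ignored — only the first
anchors, preventing double-counted days.

**Bridged gaps.** Days between a code-11 discharge and its ≤30-day reentry
are kept in the episode span by default: downstream flags remove most of
them anyway (they are typically hospital days), and dropping them would
break the simple `day_index = date − start + 1` contract. Setting
`drop_out_of_facility_gaps=true` splits episodes at gaps instead (interior
segments carry end reason `gap_split`). Consequently the containment
property "admission-anchored days ⊆ entry-anchored days" holds exactly under
the gap-dropping configuration and up to bridged gap days under the default.

**Merging, closure, death.** Episodes of one resident and anchor type merge
when one starts on or before another's end (adjacent episodes — next start =
end + 1 — stay separate); the merged span runs first start to last end, and
merging is idempotent and order-insensitive. Open episodes close at study
end. Episodes are truncated at the recorded death date; episodes starting
after death are dropped with a logged warning. Episodes are closed date
intervals: the entry date is day 1 and the end date counts as an NH day
(`count_discharge_day=false` removes the discharge day from
final-discharge episodes).

## Day-level flags

* **Enrollment** is judged per calendar month (the granularity of Medicare
  enrollment summary files): a day is enrolled iff its resident-month row
  has `part_a = part_b = part_d = 1` and `managed_care = 0`. Months absent
  from the table count as unenrolled — observability is never asserted
  without evidence. Daily-interval enrollment inputs are accepted via
  `enrollment_granularity="day"`.
* **Part A stays** (SNF and inpatient) cover the half-open span
  `[admit, discharge)`, so length of stay = discharge − admit and the
  discharge day belongs to the next care setting; `include_discharge_day`
  switches to the closed convention for sensitivity analyses. Missing
  discharge dates are imputed as `admit + length_of_stay`; rows missing both
  fields are rejected with an error record. Overlapping stays of one type
  act as a union, and a day may be SNF- and hospital-flagged simultaneously.
* Flagging steps commute: each writes only its own column.

## Observable time and reporting

Observable days satisfy `enrolled ∧ ¬snf ∧ ¬hospital`. Removal counts are
logged per reason with multi-reason days incrementing each reason (SNF and
hospital tallies are taken among enrolled days, mirroring stepwise attrition
accounting), while the unique-removal total counts each day once. Maximal
runs of consecutive dates within one parent NH episode become observable
episodes; runs never bridge even a one-day gap and never span two parent
episodes, so a discharge/readmission pair yields separate observable
episodes even when adjacent in calendar time.

Attrition tables report per time-since-admission bin (days 1–30, 31–60,
61–100, 101+ — bins partition day indices, so day counts sum to the overall
row; resident/episode counts are "≥1 qualifying day in bin" and do not).
Percentages are `100 × observable/enrolled` and `100 × observable/total`,
printed to one decimal with half-away-from-zero rounding (this choice
reproduces published accounting percentages exactly from their printed
numerators and denominators); zero denominators report as absent, not 0.

**Long-stay comparator.** The standard "method 2" classifier is implemented
as a day-index cutoff (default 101, the CMS convention tied to the 100-day
Part A benefit): an episode is long-stay iff it reaches the cutoff day, with
person-time attributed from the cutoff day onward (`from_cutoff`, default)
or to the whole episode. The original method's internals (qualifying
assessments, consecutive- vs cumulative-day subtleties) are not fully
specified in the sources this package follows, so the classifier is a
labeled approximation with the cutoff and attribution exposed as config.
Monthly comparisons count residents with ≥1 qualifying day in the month
(a point-in-time single-day definition is also conceivable; any-day-in-month
was chosen as the more stable statistic at desk scale). Drug point
prevalence in a month = residents with a dispensing whose supply interval
`[fill, fill + supply − 1]` touches one of their observable days in the
month, over residents with ≥1 observable day in the month.

## Synthetic cohort generator

The generator emulates the *structure* of linked Medicare/MDS data, not its
marginal distributions: per resident it draws admissions (Poisson, mean 1.5,
min 1), NH lengths of stay (lognormal, median 31 days, σ = 0.9 — median
matching the national cohort this package emulates, σ chosen to give the
heavy right tail typical of NH stays), SNF lead-ins starting on the entry
date (lognormal median 20 days, 40% of admissions with none, clipped to the
100-day Part A cap), hospitalizations (1/episode-year, lognormal median 5
days) optionally followed by post-acute SNF, code-11 discharge/reentry pairs
(15% of long-enough admissions, uniform 1–45 day gaps, so both bridged and
new-admission returns occur), monthly enrollment gaps (5%/resident-month)
and managed-care months (15%), deaths (25% of residents, 0–30 days after the
final discharge or inside an open episode, exercising truncation both ways),
and missing Part A discharge dates (2% of stay rows). Hospitalization and
SNF lead-in frequency/duration defaults are placeholders exposed as
parameters, not estimates. Dispensing records (rate 0.6 fills/30 NH days,
supplies in {7, 14, 30, 90}, 20% labeled gabapentin) exist only to feed the
prevalence comparator; `dispensing_rate`/`gabapentin_share` are generator
conveniences with no real-data calibration.

Stays that would run past the study window keep the half-open convention by
allowing the discharge date to fall at most on the day after study end, so
`discharge − admit = length_of_stay` stays exact.

What passing tests on synthetic data do **not** show: realism of diagnosis
mixes, facility effects, benefit-exhaustion dynamics (days 21–100
coinsurance), or Medicare Advantage encounter behavior. They do show the
algorithmic contracts — every structural feature the generator produces is
processed correctly, verified bit-for-bit against brute-force per-day
oracles on hundreds of seeded cohorts.

## Numerical and engineering choices

* All randomness flows through one `numpy` generator seeded from
  `SimParams.seed`; identical parameters give byte-identical tables.
* Episode ids are `resident:counter` ordered by start date, so ids are
  stable under partitioning. Partitions are assigned by MD5 hash of the
  resident id (never by date — every step is per-resident), and final
  outputs are canonically sorted, making them invariant to `n_partitions`.
  The run manifest records per-step row/removal counts, per-partition sizes,
  SHA-256 output checksums, and wall time per step.
* Degenerate inputs: empty cohorts produce typed empty tables and an
  all-zero attrition summary with absent percentages; orphan discharges are
  skipped with a logged count; `day_index < 1`, overlapping episodes at
  expansion, unpopulated flags at selection, and duplicate resident-months
  all raise rather than guess.
* Test problem sizes: the oracle-equivalence suite runs 200 seeded cohorts
  of 2–16 residents over 4–12-month windows against pure-python triple-loop
  oracles; the closed-form SNF lead-in recovery uses constant 50-day stays
  so the lead-in never outlives its episode, making
  `observable = Σ max(0, L − k)` exact under death and study-end truncation.

## Known limitations

Only prescription claims logic is modeled — out-of-pocket, VA-paid and
over-the-counter use stay invisible by construction. Enrollment at month
granularity cannot represent mid-month coverage changes (daily-interval
input exists for sources that have them). The long-stay comparator is an
approximation as described above. The generator's admission spacing and
event rates are convenience defaults; conclusions about real cohorts
require real linked data processed through the same pipeline surface.
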