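# comorbtraj

Comorbidity-trajectory analysis around an index diagnosis, built for
epidemiologists working with multi-source coded health records (primary
care, hospital episodes, death and cancer registries). Given a participant
table and a dated, sourced event stream, the package:

1. **resolves first occurrences** — the earliest *valid* record of each
   condition per participant, excluding self-reported records and records
   dated before birth, after the censor date, or on a registry placeholder
   sentinel;
2. **builds the index cohort** — participants carrying the index condition
   (heart failure by default), with age at index and follow-up annotated;
3. **computes trajectory statistics** — for each of 16 common long-term
   conditions, the signed time between its first diagnosis and the index
   diagnosis, `t = (d_condition − d_index) / 365.25` years (negative =
   before); per-condition timing quartiles (median, Q1–Q3); the index
   diagnosis's *sequence position* (1 + number of strictly earlier
   diagnoses); mean cumulative comorbidity-count (accrual) curves with 95%
   CIs over the at-risk population; and the diagnoses immediately before,
   synchronous with, and immediately after the index event, with a Sankey
   link list;
4. **runs the stratified test battery** — sex and age-at-index strata
   (<50, 50–60, 60–70, 70–80, 80–90 years), unpaired t / Mann–Whitney /
   chi-squared / Kruskal–Wallis tests with Bonferroni control (α/m), and a
   minimum-follow-up sensitivity restriction;
5. **reports with disclosure masking** — counts below a threshold (50 by
   default) are rendered `<50` while percentages remain.

Because real record linkages of this kind are access-controlled, the
package ships a **calibrated synthetic-cohort generator**: per-condition
lifetime prevalences and quartile-anchored timing distributions (a
piecewise-linear quantile function through the published Q1/median/Q3 with
exponential tails, so coincident anchors yield a genuine point mass at
zero offset), multi-source duplicates, self-report and invalid-date noise,
a 64/36 male/female split and age at index ~ N(69.8, 9.9²) truncated to
(35, 95). Every cohort comes with a ground-truth table, so first-occurrence
resolution can be tested for *exact* recovery.

## Worked example

```python
import comorbtraj as ct

cfg = ct.load_config(n_participants=5000, seed=1)     # packaged calibration
participants, events, truth = ct.generate_cohort(cfg)
events = ct.corrupt_events(events, truth, cfg)        # duplicates, self reports, bad dates

occ = ct.resolve_first_occurrences(events, participants)
cohort = ct.build_cohort(occ, participants, cfg.index_condition)

summary = ct.cohort_summary(cohort)
print(round(summary.mean_comorbidity_count, 2))       # 3.91

rel = ct.relative_times(cohort)
print(ct.timing_table(rel).round(1).head(3).to_string(index=False))
```

prints

```
3.91
     condition    n  median    q1   q3  iqr
osteoarthritis 1462    -7.1 -13.0 -1.6 11.5
    depression  757    -5.3 -14.5 -0.5 14.0
       obesity 1487    -4.1 -10.9 -0.1 10.7
```

i.e. the synthetic cohort averages 3.91 comorbidities per person (the sum
of the calibrated prevalences) and osteoarthritis is the earliest
forerunner of the index diagnosis, a median 7.1 years before it here
(calibration anchor −6.9, recovered within Monte-Carlo error at n=1462).
`ct.sequence_positions(cohort).median()` gives 4.0 — the index condition is
typically the fourth diagnosis — and
`ct.transition_table(ct.transitions(cohort))` tallies the diagnoses
immediately before/after it (atrial fibrillation/flutter leads at 24.8%
before, in this draw).

The same pipeline runs from the shell:

```bash
comorbtraj simulate --out data/ --n 5000 --seed 1
comorbtraj analyze --participants data/participants.csv --events data/events.csv --out results/
comorbtraj sensitivity --participants data/participants.csv --events data/events.csv \
    --out results_sens/ --cutoff 2019-04-24
```

`analyze` writes the full bundle: masked and numeric cohort-summary tables,
timing summaries, sequence-position histograms, accrual curves, ridgeline
density data, transition tables, Sankey links (JSON) and a run log with
filter-step counts.

## Input formats

- `participants.csv`: `participant_id, sex, birth_year, birth_month,
  death_date, censor_date` (dates ISO 8601; birth day is imputed as the
  1st of the month).
- `events.csv`: `participant_id, condition, event_date, source` with
  `source ∈ {primary_care, hospital, death_registry, cancer_registry,
  self_report}`.

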