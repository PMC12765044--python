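# Methods

## The analysis model

The package studies *when* long-term conditions are first diagnosed
relative to an index condition. All statistics are functions of one
derived quantity per (participant, comorbidity): the signed offset

    t = (first_diagnosis_date − index_diagnosis_date) / 365.25   [years]

with negative values before the index diagnosis. The convention of
365.25 days/year is used everywhere dates are converted to years (ages,
follow-up, offsets), so results are bit-reproducible across code paths.

Derived statistics:

- **Timing quartiles** per condition: median and Q1/Q3 by the
  linear-interpolation quantile rule (the default of mainstream numerical
  stacks). The rule is a documented choice; published analyses rarely
  state theirs, and different rules move quartiles by at most the gap
  between adjacent order statistics.
- **Sequence position**: 1 + the number of comorbidities first diagnosed
  *strictly* before the index date. Same-day diagnoses are positional
  ties, not predecessors — consistent with treating "synchronous" as its
  own category in the transition table. The alternative (counting
  same-day diagnoses as predecessors) is a one-line change in
  `sequence_position`; day resolution is the finest grain the data carry.
- **Accrual curves**: at each grid time t, the mean (±1.96·sd/√n) number
  of comorbidities with offset ≤ t among participants *at risk* at t.
  Everyone is at risk at t ≤ 0 (the full pre-index lifecourse is observed
  for cohort members); for t > 0 a participant is at risk while t does not
  exceed their post-index follow-up. With fewer than two at-risk
  participants the CI is undefined (NaN). Default grid −25 to +15 years in
  0.25-year steps. Note the post-index portion describes a shrinking,
  survivor-biased population; the package reports `n_at_risk` alongside
  the mean so readers can judge this.
- **Adjacent diagnoses**: per participant, the comorbidity with the
  latest first date strictly before the index date, the earliest strictly
  after, and the set dated the same day ("synchronous"). Exact date ties
  are broken by a fixed condition-priority list (the transition-table row
  order, dementia → … → osteoarthritis); the number of ties broken is
  logged. Sankey links pair before → after per participant and exclude
  synchronous diagnoses, which rarely represent new preventive
  opportunities.

## First-occurrence resolution

A condition's first occurrence is the minimum valid event date over the
accepted sources (primary care, hospital, death registry, cancer
registry; self report excluded). A date is invalid when it precedes the
imputed birth date (equality is allowed — "prior to birth" is read
strictly), follows the participant's censor date (the only operational
definition of "in the future" available), or equals a registry
placeholder sentinel (defaults 1900-01-01, 1901-01-01, 2037-07-07; fully
configurable). Birth day is imputed as the 1st of the birth month —
deterministic and at most ~30 days off, matching month-resolution birth
fields. When several accepted sources share the earliest date the
resolved date is unaffected; only the provenance label follows the fixed
priority primary_care > hospital > death_registry > cancer_registry.
Cancer-registry records are accepted for any condition — resolution stays
source-agnostic; it is the generator that only emits them for cancer.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real population:

- every participant carries the index condition; sex ~ Bernoulli(0.64
  male), age at index ~ Normal(69.8, 9.9²) truncated to (35, 95) years
  (the bounds span the age strata with margin);
- the index *calendar* date is drawn uniformly over 2000-01-01 to
  2014-12-31 and every censor date is the study end (2024-04-24), so each
  participant has at least ~9.3 years of potential post-index follow-up;
  the calendar placement is otherwise immaterial to index-relative
  statistics;
- each comorbidity is present independently with its lifetime prevalence;
  the expected comorbidity count is therefore exactly the prevalence sum
  (3.912 under the packaged calibration);
- a present comorbidity's date is the index date plus an offset drawn
  from the quantile-anchored sampler, rounded to whole days (EHR dates
  are day-resolved);
- offsets are redrawn until the date falls inside the observable window
  (after the imputed birth date, on or before the censor date). This
  window truncation keeps the ground-truth table exactly recoverable by
  the resolver and preserves prevalence; under the default index window
  the per-condition rejection probability is at most a few percent, so
  quartiles are essentially unaffected (the parameter-recovery test suite
  checks the *samplers*, and cohort-level quartiles pass the same checks
  at looser Monte-Carlo tolerance).

**Quantile-anchored sampler.** Q(u) is piecewise linear through
(0.25, q1), (0.5, median), (0.75, q3). Below u=0.25 and above u=0.75 the
tails are exponential with rate 0.2/year by default — the published
quartiles do not constrain the tails, and the rate only shapes the outer
25% of mass on each side, leaving the anchors invariant. Coincident
anchors make Q flat on the corresponding u-interval, producing a point
mass of 0.25 per flat segment; this is how a published quartile of
exactly 0.0 years (diagnosis synchronous with the index event) is
reproduced structurally rather than by a separate mixture weight, which
guarantees quartile recovery by construction.

**Corruption pass.** Per true occurrence, independently: a hospital
duplicate dated 0–3 years later (probability 0.3), a self-report record
possibly *earlier* than the true date (0.1) — so resolution must exclude
it by source, not by date — and a record with a placeholder, pre-birth or
post-censor date (0.05). None of these can change a correct resolver's
output, which is the oracle-closure property the occurrence tests assert
exactly across seeds.

**What the generator does not emulate.** Conditions are independent given
the index date; real comorbidities cluster, which is why the generated
count *dispersion* (sd ≈ 1.64) is narrower than real cohorts (≈ 2.07)
even though the mean matches. There is no death process (censoring is
administrative for everyone; an age- or burden-dependent death hazard is
a possible extension, deliberately off by default because the underlying
mortality process is unobservable from the published summaries), no
recording delay distinct from onset, no secular trends, and synchronous
coding bursts arise only from flat quantile segments rather than from
health-contact clustering. Passing tests therefore validate the
*machinery* — resolution, timing arithmetic, stratification, masking —
not any epidemiological claim about a real population.

## Stratified testing

Age strata are half-open on the left boundary ([50, 60), …, [80, 90));
a boundary convention is required because rendered labels overlap, and
50.0 belonging to "50–60" is the documented choice. Ages ≥ 90 receive an
explicit `out_of_range` label rather than a silent drop. The test per
variable (t, Mann–Whitney, chi-squared, Kruskal–Wallis) is declared by
the caller, mirroring fixed analytic choices rather than automated
normality testing — reproducibility over automation. Chi-squared tests
use no continuity correction by default (large samples; a switch is
provided). The 16-condition battery is Bonferroni-controlled at α/m
(0.003125 for α=0.05, m=16, i.e. 0.003 at three decimals); an all-null
simulation suite confirms family-wise error ≤ 5%.

The minimum-follow-up sensitivity analysis retains participants whose
index diagnosis is on or before a cutoff date. It is idempotent and
monotone in the cutoff; on synthetic cohorts it shifts timing medians
toward/past zero, as expected when post-index observation lengthens while
the pre-index record cannot.

## Reporting

Counts below the disclosure threshold (50) are rendered `<50` with the
percentage still shown; numeric companion tables retain full precision,
and every rendered percentage recomputes from its unmasked count. Ridgeline
densities use a Gaussian KDE with Silverman's bandwidth per condition,
normalized to unit area (amplitude deliberately unrelated to prevalence)
and ordered by median timing; a zero-variance condition falls back to a
fixed 0.25-year Gaussian bump, since a KDE is undefined there. Rendered
tables round years and percentages to one decimal and counts-means to
two; machine-readable outputs are full precision.

## Problem sizes

The test suite exercises cohorts of 150–1,500 participants (plus one
n=10,000 mean-recovery check), 100,000-draw sampler recoveries, a 20-seed
oracle-closure sweep, 1,000 brute-force sequence-position cases and 1,000
all-null battery replicates — sizes at which every Monte-Carlo tolerance
(3–4 standard errors) is meaningfully tight while the suite stays quick.
`scripts/acceptance.py` uses n=10,000 cohorts and 100,000-draw samplers.
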