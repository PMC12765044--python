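# Default synthetic-cohort calibration: a heart-failure index cohort with
# 16 comorbidities.  Prevalences are lifetime fractions of the cohort;
# q1/median/q3 are quartile anchors (years relative to the index diagnosis,
# negative = before) of each condition's first-diagnosis timing.
n_participants: 10000
male_fraction: 0.64
index_age_mean: 69.8
index_age_sd: 9.9
index_age_bounds: [35.0, 95.0]
index_window: ["2000-01-01", "2014-12-31"]
study_end: "2024-04-24"
index_condition: heart_failure
duplicate_record_prob: 0.30
self_report_prob: 0.10
invalid_date_prob: 0.05
placeholder_dates: ["1900-01-01", "1901-01-01", "2037-07-07"]
seed: 20240424
conditions:
  osteoarthritis:              {prevalence: 0.283, q1: -12.9, median: -6.9, q3: -1.5}
  depression:                  {prevalence: 0.159, q1: -14.4, median: -4.6, q3: 0.0}
  obesity:                     {prevalence: 0.300, q1: -11.2, median: -3.8, q3: 0.0}
  cancer:                      {prevalence: 0.347, q1: -11.6, median: -3.8, q3: 0.0}
  diabetes:                    {prevalence: 0.303, q1: -10.3, median: -3.4, q3: 0.0}
  hypertension:                {prevalence: 0.391, q1: -9.8,  median: -2.6, q3: 0.0}
  thyroid_disease:             {prevalence: 0.115, q1: -10.2, median: -1.7, q3: 0.7}
  asthma:                      {prevalence: 0.076, q1: -7.4,  median: -1.3, q3: 0.6}
  anaemia:                     {prevalence: 0.360, q1: -6.1,  median: -0.3, q3: 0.9}
  atrial_fibrillation:         {prevalence: 0.511, q1: -3.9,  median: -0.1, q3: 0.0}
  chronic_renal_failure:       {prevalence: 0.323, q1: -6.4,  median: 0.0,  q3: 2.0}
  peripheral_arterial_disease: {prevalence: 0.111, q1: -4.8,  median: 0.0,  q3: 1.4}
  copd:                        {prevalence: 0.194, q1: -3.6,  median: 0.0,  q3: 1.5}
  myocardial_infarction:       {prevalence: 0.270, q1: -2.4,  median: 0.0,  q3: 0.0}
  stroke:                      {prevalence: 0.104, q1: -3.2,  median: 0.0,  q3: 2.9}
  dementia:                    {prevalence: 0.065, q1: -0.1,  median: 0.7,  q3: 4.8}
# Sex-specific median timing anchors (years), for stratified calibrations:
# cancer is diagnosed a median 7.1 years before the index event in women
# versus 2.6 years in men.
sex_stratified_medians:
  female:
    cancer: -7.1
  male:
    cancer: -2.6
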