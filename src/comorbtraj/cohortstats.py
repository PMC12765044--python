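"""Stratification and the hypothesis-test battery.

The cohort is stratified by sex and by age at the index diagnosis
(<50, 50–60, 60–70, 70–80, 80–90 years; half-open on the left boundary).
Between-sex comparisons use unpaired t-tests (normal continuous),
Mann–Whitney tests (non-normal continuous) or chi-squared tests
(categorical, no continuity correction by default); across age strata,
Kruskal–Wallis.  Family-wise error over the 16-condition battery is
controlled by Bonferroni (alpha / m).  A sensitivity helper restricts the
cohort to participants diagnosed early enough to guarantee a minimum
post-index observation period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InputError
from .occurrence import Cohort

logger = logging.getLogger(__name__)

OUT_OF_RANGE = "out_of_range"

#: (label, lower inclusive, upper exclusive); <50 is open below at 0.
AGE_STRATA: tuple[tuple[str, float, float], ...] = (
    ("<50", 0.0, 50.0),
    ("50–60", 50.0, 60.0),
    ("60–70", 60.0, 70.0),
    ("70–80", 70.0, 80.0),
    ("80–90", 80.0, 90.0),
)

STRATUM_LABELS: tuple[str, ...] = tuple(label for label, _, _ in AGE_STRATA)


def assign_age_stratum(age_at_index: float) -> str:
    """Age-at-index stratum label; ages ≥ 90 map to ``out_of_range``."""
    age = float(age_at_index)
    if not np.isfinite(age) or age <= 0:
        raise InputError(f"age at index must be finite and positive, got {age_at_index}")
    for label, lo, hi in AGE_STRATA:
        if lo <= age < hi:
            return label
    return OUT_OF_RANGE


def assign_age_strata(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_stratum`."""
    a = ages.to_numpy(float)
    if np.any(~np.isfinite(a) | (a <= 0)):
        raise InputError("age at index must be finite and positive for every participant")
    out = np.full(a.shape, OUT_OF_RANGE, dtype=object)
    for label, lo, hi in AGE_STRATA:
        out[(a >= lo) & (a < hi)] = label
    return pd.Series(out, index=ages.index, name="age_stratum")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling family-wise error at
    *alpha* over *m* tests (alpha / m)."""
    if m < 1:
        raise InputError("number of tests m must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class TestResult:
    comparison: str
    test: str  # "t" | "mann_whitney" | "chi_squared" | "kruskal_wallis"
    statistic: float
    p_value: float
    significant: bool
    threshold: float


def compare_by_sex(
    cohort_df: pd.DataFrame,
    variable: str,
    test: str,
    threshold: float = 0.05,
    yates_correction: bool = False,
) -> TestResult:
    """Compare *variable* between the sexes with the declared test.

    ``t`` and ``mann_whitney`` expect a continuous column; ``chi_squared``
    expects a binary/categorical column and uses no continuity correction
    unless *yates_correction* is set.  The test per variable is declared by
    the caller rather than inferred from a normality test, so analyses are
    exactly reproducible.
    """
    groups = {sex: g[variable].dropna() for sex, g in cohort_df.groupby("sex")}
    for sex in ("male", "female"):
        if sex not in groups or len(groups[sex]) == 0:
            raise InputError(f"compare_by_sex: no observations in group '{sex}'")
    male, female = groups["male"], groups["female"]

    if test == "t":
        stat, p = stats.ttest_ind(male, female, equal_var=True)
    elif test == "mann_whitney":
        stat, p = stats.mannwhitneyu(male, female, alternative="two-sided")
    elif test == "chi_squared":
        table = pd.crosstab(cohort_df["sex"], cohort_df[variable])
        stat, p, _, _ = stats.chi2_contingency(table, correction=yates_correction)
    else:
        raise InputError(f"unknown between-sex test '{test}'")
    return TestResult(
        comparison=f"{variable} by sex",
        test=test,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < threshold),
        threshold=threshold,
    )


def compare_across_age_strata(
    cohort_df: pd.DataFrame,
    variable: str,
    threshold: float = 0.05,
    stratum_column: str = "age_stratum",
) -> TestResult:
    """Kruskal–Wallis comparison of *variable* across age-at-index strata."""
    samples = [
        g[variable].dropna().to_numpy()
        for label, g in cohort_df.groupby(stratum_column)
        if label in STRATUM_LABELS and len(g[variable].dropna())
    ]
    if len(samples) < 2:
        raise InputError("compare_across_age_strata: need at least two non-empty strata")
    stat, p = stats.kruskal(*samples)
    return TestResult(
        comparison=f"{variable} across age strata",
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < threshold),
        threshold=threshold,
    )


def condition_battery(
    cohort: Cohort,
    conditions: tuple[str, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-sex prevalence tests for each condition at the Bonferroni
    threshold alpha/m (m = number of conditions).  Returns the delimited
    battery table: comparison, test, statistic, p, significant."""
    thr = bonferroni_threshold(alpha, len(conditions))
    flags = cohort.participants[["participant_id", "sex"]].copy()
    has = cohort.occurrences.groupby("participant_id")["condition"].agg(set)
    rows = []
    for cond in conditions:
        flags["_has"] = [
            cond in has.get(pid, set()) for pid in flags["participant_id"]
        ]
        res = compare_by_sex(flags, "_has", "chi_squared", threshold=thr)
        rows.append(
            {
                "comparison": f"{cond} prevalence by sex",
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "threshold": thr,
            }
        )
    return pd.DataFrame(rows)


def apply_min_followup(cohort: Cohort, cutoff_date) -> Cohort:
    """Sensitivity restriction: keep participants whose index diagnosis is
    on or before *cutoff_date*, guaranteeing a minimum observation period
    after the index event for those not dying earlier.  Idempotent and
    monotone in the cutoff."""
    cutoff = pd.Timestamp(cutoff_date)
    keep = cohort.participants["index_date"] <= cutoff
    if not keep.any():
        logger.warning("apply_min_followup: cutoff %s precedes every index date", cutoff.date())
    participants = cohort.participants[keep].reset_index(drop=True)
    members = set(participants["participant_id"])
    occurrences = cohort.occurrences[
        cohort.occurrences["participant_id"].isin(members)
    ].reset_index(drop=True)
    frac = len(participants) / cohort.size if cohort.size else float("nan")
    return Cohort(participants, occurrences, cohort.index_condition, frac)
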