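"""Index-relative trajectory statistics.

All timings are signed offsets in years from the index diagnosis
(negative = before), converted from day counts at 365.25 days/year.
The module computes: per-condition timing quartiles, the position of the
index diagnosis in each participant's disease sequence, mean cumulative
comorbidity-count (accrual) curves with at-risk denominators, and the
diagnoses immediately before / synchronous with / immediately after the
index event, including the Sankey link list that summarizes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import TRANSITION_PRIORITY
from .occurrence import Cohort
from .synthgen import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

NONE_LABEL = "none"


def relative_time_years(occurrence_date, index_date) -> float:
    """Signed years between an occurrence and the index diagnosis
    (day count / 365.25; negative = occurrence precedes the index)."""
    delta = pd.Timestamp(occurrence_date) - pd.Timestamp(index_date)
    return delta.days / DAYS_PER_YEAR


def relative_times(cohort: Cohort) -> pd.DataFrame:
    """Long table of signed comorbidity timings for a cohort:
    ``participant_id, condition, years_from_index``."""
    merged = cohort.occurrences.merge(
        cohort.participants[["participant_id", "index_date"]], on="participant_id"
    )
    merged["years_from_index"] = (
        (merged["first_date"] - merged["index_date"]).dt.days / DAYS_PER_YEAR
    )
    return merged[["participant_id", "condition", "years_from_index"]]


def sequence_position(participant_occurrences: pd.DataFrame, index_condition: str) -> int:
    """Position of the index diagnosis in one participant's chronological
    disease sequence: 1 + the number of comorbidities first diagnosed
    strictly before the index date.  Same-day diagnoses are positional
    ties and do not count as predecessors.
    """
    rows = participant_occurrences
    idx = rows.loc[rows["condition"] == index_condition, "first_date"]
    if len(idx) == 0:
        raise ValueError("participant has no index occurrence")
    index_date = idx.iloc[0]
    others = rows[rows["condition"] != index_condition]
    return 1 + int((others["first_date"] < index_date).sum())


def sequence_positions(cohort: Cohort) -> pd.Series:
    """Vectorized :func:`sequence_position` over a cohort (indexed by
    participant_id; every cohort member appears, including those with no
    comorbidities)."""
    rel = relative_times(cohort)
    prior = (
        rel[rel["years_from_index"] < 0].groupby("participant_id").size()
    )
    pos = prior.reindex(cohort.participants["participant_id"], fill_value=0) + 1
    pos.name = "sequence_position"
    return pos.astype(int)


@dataclass(frozen=True)
class TimingSummary:
    condition: str
    n: int
    median: float
    q1: float
    q3: float


def timing_summary(rel_times: pd.DataFrame, condition: str) -> TimingSummary | None:
    """Median and quartiles (linear-interpolation rule) of one condition's
    index-relative timing; None (with a warning) when unobserved."""
    x = rel_times.loc[rel_times["condition"] == condition, "years_from_index"].to_numpy(float)
    if x.size == 0:
        logger.warning("timing_summary: no observations for %s; omitted", condition)
        return None
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # default linear interpolation
    return TimingSummary(condition=condition, n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))


def iqr_width(summary: TimingSummary) -> float:
    """Interquartile range (q3 − q1) in years."""
    return summary.q3 - summary.q1


def timing_table(rel_times: pd.DataFrame, order: str = "median") -> pd.DataFrame:
    """Per-condition timing summaries as a DataFrame, sorted ascending by
    median (the ridgeline ordering) unless ``order=None``."""
    rows = []
    for cond in rel_times["condition"].unique():
        s = timing_summary(rel_times, cond)
        if s is not None:
            rows.append(
                {"condition": s.condition, "n": s.n, "median": s.median, "q1": s.q1,
                 "q3": s.q3, "iqr": iqr_width(s)}
            )
    table = pd.DataFrame(rows, columns=["condition", "n", "median", "q1", "q3", "iqr"])
    if order == "median" and len(table):
        table = table.sort_values(["median", "condition"], kind="mergesort").reset_index(drop=True)
    return table


@dataclass
class AccrualCurve:
    """Mean cumulative comorbidity count against time relative to the index
    diagnosis, over the at-risk population at each grid time."""

    stratum: str
    grid: np.ndarray
    mean_count: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "years_from_index": self.grid,
                "mean_count": self.mean_count,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
            }
        )


def default_accrual_grid(start: float = -25.0, stop: float = 15.0, step: float = 0.25) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 10)


def accrual_curve(
    rel_times: pd.DataFrame,
    follow_up_years: pd.Series,
    grid: np.ndarray | None = None,
    stratum: str = "all",
) -> AccrualCurve:
    """Accrual curve for one (sub)cohort.

    *follow_up_years* is indexed by participant_id and defines the cohort:
    every listed participant contributes at all t ≤ 0; for t > 0 only those
    still under observation (t ≤ follow-up) remain in the denominator.
    The CI is the normal approximation mean ± 1.96·sd/√n, undefined (NaN)
    where fewer than two participants are at risk.
    """
    if grid is None:
        grid = default_accrual_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    pids = follow_up_years.index.to_numpy()
    n = len(pids)
    if n == 0:
        empty = np.array([])
        return AccrualCurve(stratum, grid, *(np.full(grid.size, np.nan),) * 3, np.zeros(grid.size, int))

    # per-participant cumulative counts via searchsorted on sorted offsets
    counts = np.zeros((n, grid.size), dtype=float)
    grouped = {pid: g["years_from_index"].to_numpy() for pid, g in rel_times.groupby("participant_id")}
    for i, pid in enumerate(pids):
        times = grouped.get(pid)
        if times is not None and times.size:
            counts[i] = np.searchsorted(np.sort(times), grid, side="right")

    fup = follow_up_years.to_numpy(float)
    at_risk = (grid[None, :] <= 0) | (grid[None, :] <= fup[:, None])
    n_at_risk = at_risk.sum(axis=0)

    mean = np.full(grid.size, np.nan)
    lo = np.full(grid.size, np.nan)
    hi = np.full(grid.size, np.nan)
    for j in range(grid.size):
        if n_at_risk[j] == 0:
            continue
        vals = counts[at_risk[:, j], j]
        mean[j] = vals.mean()
        if n_at_risk[j] >= 2:
            se = vals.std(ddof=1) / np.sqrt(n_at_risk[j])
            lo[j] = mean[j] - 1.96 * se
            hi[j] = mean[j] + 1.96 * se
    return AccrualCurve(stratum, grid, mean, lo, hi, n_at_risk.astype(int))


@dataclass
class TransitionRecord:
    """One participant's diagnoses adjacent to the index event."""

    participant_id: str
    before: str | None
    synchronous: tuple[str, ...]
    after: str | None


def adjacent_diagnoses(
    participant_occurrences: pd.DataFrame,
    index_condition: str,
    priority: tuple[str, ...] = TRANSITION_PRIORITY,
) -> TransitionRecord:
    """The comorbidity immediately before the index diagnosis (latest
    strictly-earlier first date), immediately after (earliest strictly-later),
    and all synchronous (same calendar day) diagnoses.  Exact date ties are
    broken by the fixed condition priority list."""
    rows = participant_occurrences
    idx = rows.loc[rows["condition"] == index_condition]
    if len(idx) == 0:
        raise ValueError("participant has no index occurrence")
    pid = idx["participant_id"].iloc[0]
    index_date = idx["first_date"].iloc[0]
    others = rows[rows["condition"] != index_condition].copy()
    rank = {c: i for i, c in enumerate(priority)}
    others["_rank"] = others["condition"].map(lambda c: rank.get(c, len(priority)))

    prior = others[others["first_date"] < index_date]
    before = None
    if len(prior):
        best = prior.sort_values(["first_date", "_rank"], ascending=[False, True], kind="mergesort")
        before = best["condition"].iloc[0]
    later = others[others["first_date"] > index_date]
    after = None
    if len(later):
        best = later.sort_values(["first_date", "_rank"], ascending=[True, True], kind="mergesort")
        after = best["condition"].iloc[0]
    sync = others[others["first_date"] == index_date].sort_values("_rank", kind="mergesort")
    return TransitionRecord(pid, before, tuple(sync["condition"]), after)


def transitions(cohort: Cohort, priority: tuple[str, ...] = TRANSITION_PRIORITY) -> pd.DataFrame:
    """Vectorized adjacent-diagnosis resolution for a whole cohort.

    Returns one row per cohort participant: ``participant_id, before,
    synchronous`` (tuple) ``, after``; ``before``/``after`` are
    :data:`NONE_LABEL` when no qualifying diagnosis exists.  The number of
    exact date ties encountered is logged.
    """
    occ = cohort.occurrences.merge(
        cohort.participants[["participant_id", "index_date"]], on="participant_id"
    )
    occ["_days"] = (occ["first_date"] - occ["index_date"]).dt.days
    rank = {c: i for i, c in enumerate(priority)}
    occ["_rank"] = occ["condition"].map(lambda c: rank.get(c, len(priority)))

    prior = occ[occ["_days"] < 0].sort_values(
        ["participant_id", "_days", "_rank"], ascending=[True, True, False], kind="mergesort"
    )
    n_ties = int(prior.duplicated(subset=["participant_id", "_days"]).sum())
    before = prior.groupby("participant_id")["condition"].last()

    later = occ[occ["_days"] > 0].sort_values(
        ["participant_id", "_days", "_rank"], ascending=True, kind="mergesort"
    )
    n_ties += int(later.duplicated(subset=["participant_id", "_days"]).sum())
    after = later.groupby("participant_id")["condition"].first()

    sync = (
        occ[occ["_days"] == 0]
        .sort_values(["participant_id", "_rank"], kind="mergesort")
        .groupby("participant_id")["condition"]
        .agg(tuple)
    )
    if n_ties:
        logger.info("transitions: %d exact date ties broken by condition priority", n_ties)

    pids = cohort.participants["participant_id"]
    out = pd.DataFrame(
        {
            "participant_id": pids.to_numpy(),
            "before": before.reindex(pids, fill_value=None).fillna(NONE_LABEL).to_numpy(),
            "synchronous": sync.reindex(pids).apply(lambda v: v if isinstance(v, tuple) else ()).to_numpy(),
            "after": after.reindex(pids, fill_value=None).fillna(NONE_LABEL).to_numpy(),
        }
    )
    return out


def transition_table(
    transition_records: pd.DataFrame,
    conditions: tuple[str, ...] = TRANSITION_PRIORITY,
) -> pd.DataFrame:
    """Counts and cohort percentages of each condition appearing immediately
    before, synchronous with, or immediately after the index diagnosis.

    Each of the before/after columns sums to the cohort size once its
    ``none`` row is included; the synchronous column counts each
    (participant, condition) pair once and its ``none`` row counts
    participants with no synchronous diagnosis.
    """
    n = len(transition_records)
    rows = list(conditions) + [NONE_LABEL]
    out = pd.DataFrame(index=rows)
    before = transition_records["before"].value_counts()
    after = transition_records["after"].value_counts()
    sync_counts = pd.Series(
        [c for t in transition_records["synchronous"] for c in t], dtype=object
    ).value_counts()
    sync_none = int((transition_records["synchronous"].apply(len) == 0).sum())

    out["before_n"] = [int(before.get(r, 0)) for r in rows]
    out["synchronous_n"] = [
        int(sync_counts.get(r, 0)) if r != NONE_LABEL else sync_none for r in rows
    ]
    out["after_n"] = [int(after.get(r, 0)) for r in rows]
    for col in ("before", "synchronous", "after"):
        out[f"{col}_pct"] = 100.0 * out[f"{col}_n"] / n if n else np.nan
    out.index.name = "condition"
    return out.reset_index()


def sankey_links(transition_records: pd.DataFrame) -> list[dict]:
    """Link list pairing each participant's immediately-before and
    immediately-after diagnoses (synchronous diagnoses excluded), as
    ``{"source": ..., "target": ..., "value": n}`` records."""
    pairs = (
        transition_records.groupby(["before", "after"]).size().reset_index(name="value")
    )
    pairs = pairs.sort_values(["before", "after"], kind="mergesort")
    return [
        {"source": f"before:{r.before}", "target": f"after:{r.after}", "value": int(r.value)}
        for r in pairs.itertuples()
    ]
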