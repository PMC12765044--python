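"""First-occurrence resolution from a multi-source coded event stream.

Coded health records assert the same diagnosis many times across sources
(primary care, hospital episodes, death registry, cancer registry,
self report).  The analysis needs one row per (participant, condition):
the earliest *valid* record from an *accepted* source.  Self-reported
occurrences are excluded, as are records dated before birth, after the
participant's censor date, or carrying a registry placeholder sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import pandas as pd

from ._errors import InputError, OrphanParticipantError
from .synthgen import DAYS_PER_YEAR, DEFAULT_PLACEHOLDER_DATES

logger = logging.getLogger(__name__)

SOURCES: tuple[str, ...] = (
    "primary_care",
    "hospital",
    "death_registry",
    "cancer_registry",
    "self_report",
)

#: Default accepted sources: everything except self report.
DEFAULT_ALLOWED_SOURCES: tuple[str, ...] = SOURCES[:-1]

#: Same-date ties are labelled with the most authoritative source.
_SOURCE_PRIORITY = {s: i for i, s in enumerate(SOURCES)}


def impute_birth_date(birth_year: int, birth_month: int) -> pd.Timestamp:
    """Impute a day-resolved birth date from year and month of birth.

    Record linkages typically carry only year and month of birth for
    disclosure control; the day is imputed as the 1st of the month
    (deterministic, errs by at most ~30 days).
    """
    if not 1 <= int(birth_month) <= 12:
        raise InputError(f"birth month must be in 1..12, got {birth_month}")
    return pd.Timestamp(int(birth_year), int(birth_month), 1)


def validate_event_date(event_date, birth_date, censor_date, placeholder_dates=DEFAULT_PLACEHOLDER_DATES) -> bool:
    """True iff *event_date* is usable: not before birth (equality is fine),
    not after the censor date, and not a placeholder sentinel."""
    try:
        d = pd.Timestamp(event_date)
        b = pd.Timestamp(birth_date)
        c = pd.Timestamp(censor_date)
        ph = {pd.Timestamp(p) for p in placeholder_dates}
    except (ValueError, TypeError) as exc:
        raise InputError(f"unparseable date in record ({event_date!r}): {exc}") from exc
    if pd.isna(d):
        raise InputError(f"unparseable date in record ({event_date!r})")
    return not (d < b or d > c or d in ph)


def _coerce_dates(frame: pd.DataFrame, column: str, context: str) -> pd.Series:
    raw = frame[column]
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        offenders = frame.loc[bad].head(5).to_dict("records")
        raise InputError(f"unparseable {column} in {context}: {offenders}")
    return parsed


def participant_reference_dates(participants: pd.DataFrame) -> pd.DataFrame:
    """Per participant: imputed birth date and censor date."""
    months = participants["birth_month"].astype(int)
    if ((months < 1) | (months > 12)).any():
        raise InputError("birth_month outside 1..12 in participant table")
    birth = pd.to_datetime(
        {"year": participants["birth_year"].astype(int), "month": months, "day": 1}
    )
    out = pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy(),
            "birth_date": birth.to_numpy(),
            "censor_date": _coerce_dates(participants, "censor_date", "participant table").to_numpy(),
        }
    )
    return out


def resolve_first_occurrences(
    events: pd.DataFrame,
    participants: pd.DataFrame,
    allowed_sources=DEFAULT_ALLOWED_SOURCES,
    placeholder_dates=DEFAULT_PLACEHOLDER_DATES,
) -> pd.DataFrame:
    """Resolve the earliest valid occurrence of each condition per participant.

    Returns a table with columns ``participant_id, condition, first_date,
    source``; (participant, condition) pairs with no surviving record are
    simply absent.  When several accepted sources share the earliest date,
    the date is unaffected and the provenance label follows the fixed
    priority primary_care > hospital > death_registry > cancer_registry.

    Raises :class:`OrphanParticipantError` if the event stream references
    unknown participant ids.
    """
    known = set(participants["participant_id"])
    orphans = set(events["participant_id"]) - known
    if orphans:
        raise OrphanParticipantError(orphans)

    ev = events.copy()
    if len(ev) == 0:
        return pd.DataFrame(columns=["participant_id", "condition", "first_date", "source"])
    ev["event_date"] = _coerce_dates(ev, "event_date", "event table")
    ev = ev[ev["source"].isin(allowed_sources)]

    ref = participant_reference_dates(participants)
    ev = ev.merge(ref, on="participant_id", how="left")
    ph = pd.to_datetime(list(placeholder_dates))
    valid = (
        (ev["event_date"] >= ev["birth_date"])
        & (ev["event_date"] <= ev["censor_date"])
        & ~ev["event_date"].isin(ph)
    )
    ev = ev[valid]
    if len(ev) == 0:
        return pd.DataFrame(columns=["participant_id", "condition", "first_date", "source"])

    ev = ev.assign(_rank=ev["source"].map(_SOURCE_PRIORITY))
    ev = ev.sort_values(
        ["participant_id", "condition", "event_date", "_rank"], kind="mergesort"
    )
    first = ev.groupby(["participant_id", "condition"], as_index=False, sort=True).first()
    first = first.rename(columns={"event_date": "first_date"})
    return first[["participant_id", "condition", "first_date", "source"]].reset_index(drop=True)


@dataclass
class Cohort:
    """An index-condition cohort: participants with the index diagnosis,
    their resolved comorbidity occurrences, and bookkeeping columns
    (index_date, age_at_index, follow_up_years)."""

    participants: pd.DataFrame
    occurrences: pd.DataFrame  # comorbidity occurrences only (index excluded)
    index_condition: str
    fraction: float  # share of the input population carrying the index condition

    @property
    def size(self) -> int:
        return len(self.participants)


def build_cohort(occurrences: pd.DataFrame, participants: pd.DataFrame, index_condition: str) -> Cohort:
    """Restrict to participants whose occurrence table contains the index
    condition and annotate them with index date, age at index and follow-up.
    """
    if len(participants) == 0:
        logger.warning("build_cohort: empty participant table")
        return Cohort(participants.copy(), occurrences.iloc[0:0].copy(), index_condition, float("nan"))

    idx = occurrences[occurrences["condition"] == index_condition][
        ["participant_id", "first_date"]
    ].rename(columns={"first_date": "index_date"})
    fraction = len(idx) / len(participants)

    ref = participant_reference_dates(participants)
    members = (
        participants.drop(columns=["censor_date"])
        .merge(idx, on="participant_id", how="inner")
        .merge(ref, on="participant_id", how="left")
    )
    members["age_at_index"] = (
        (members["index_date"] - members["birth_date"]).dt.days / DAYS_PER_YEAR
    )
    members["follow_up_years"] = (
        (members["censor_date"] - members["index_date"]).dt.days / DAYS_PER_YEAR
    )
    keep = occurrences["participant_id"].isin(set(idx["participant_id"])) & (
        occurrences["condition"] != index_condition
    )
    como = occurrences[keep].reset_index(drop=True)
    if len(members) == 0:
        logger.warning("build_cohort: no participant carries %s", index_condition)
    return Cohort(members.reset_index(drop=True), como, index_condition, fraction)
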