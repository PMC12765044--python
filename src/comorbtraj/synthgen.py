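"""Synthetic multi-source EHR cohort generator.

Real trajectory analyses of this kind run on access-controlled record
linkages (primary care, hospital episodes, death and cancer registries).
This module generates cohorts with the same statistical structure so the
analysis code can be tested against a known ground truth:

* every simulated participant carries the index condition;
* each of 16 comorbidities occurs independently with a configurable
  lifetime prevalence;
* the signed time between a comorbidity's first diagnosis and the index
  diagnosis is drawn from a *quantile-anchored* distribution — a piecewise
  linear quantile function forced through published quartile anchors, with
  exponential tails beyond the outer anchors.  Coincident anchors produce a
  genuine point mass (many conditions have their median and/or upper
  quartile exactly at the index date);
* a corruption pass adds the record pathologies the resolution rules must
  survive: cross-source duplicates, self-reported records, and records with
  placeholder or out-of-range dates.

A truth table of per-participant first diagnosis dates accompanies every
cohort, so downstream first-occurrence resolution can be checked exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError
from .conditions import INDEX_CONDITION

DAYS_PER_YEAR = 365.25

#: Registry-style sentinel dates that mark an unknown true date.
DEFAULT_PLACEHOLDER_DATES: tuple[str, ...] = ("1900-01-01", "1901-01-01", "2037-07-07")

DEFAULT_TAIL_RATE = 0.2  # 1/years; mean tail excursion of 5 years beyond the outer quartiles


@dataclass(frozen=True)
class TimingSpec:
    """Calibration of one condition: lifetime prevalence plus quartile anchors
    of its index-relative first-diagnosis time (negative = before the index
    diagnosis; units are years)."""

    condition: str
    prevalence: float
    q1: float
    median: float
    q3: float
    lower_tail_rate: float = DEFAULT_TAIL_RATE
    upper_tail_rate: float = DEFAULT_TAIL_RATE

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(
                f"{self.condition}: prevalence {self.prevalence} outside [0, 1]"
            )
        if not self.q1 <= self.median <= self.q3:
            raise ConfigurationError(
                f"{self.condition}: quartile anchors must satisfy q1 <= median <= q3, "
                f"got ({self.q1}, {self.median}, {self.q3})"
            )
        if self.lower_tail_rate <= 0 or self.upper_tail_rate <= 0:
            raise ConfigurationError(f"{self.condition}: tail rates must be strictly positive")

    def shifted_to_median(self, new_median: float) -> "TimingSpec":
        """Translate all three anchors so the median lands on *new_median*.

        Used to derive stratum-specific specs (e.g. a sex-specific median)
        while keeping the spread of the pooled calibration.
        """
        delta = new_median - self.median
        return replace(self, q1=self.q1 + delta, median=new_median, q3=self.q3 + delta)


class QuantileSampler:
    """Sampler defined by its quantile function.

    Q(u) is piecewise linear through (0.25, q1), (0.5, median), (0.75, q3),
    with exponential tails below u=0.25 and above u=0.75.  Wherever
    consecutive anchors coincide, Q is flat on the corresponding u-interval,
    so that value receives a point mass of probability 0.25 per flat
    segment — this is how a published quartile of exactly 0.0 years
    (diagnosis synchronous with the index event) is reproduced by
    construction.
    """

    def __init__(self, spec: TimingSpec):
        self.spec = spec

    def quantile(self, u):
        """Evaluate Q(u) for u in (0, 1); accepts scalars or arrays."""
        s = self.spec
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0.0) | (u >= 1.0)):
            raise ValueError("quantile function defined on the open interval (0, 1)")
        out = np.empty_like(u)
        lo = u < 0.25
        mid1 = (u >= 0.25) & (u < 0.5)
        mid2 = (u >= 0.5) & (u < 0.75)
        hi = u >= 0.75
        out[lo] = s.q1 + np.log(u[lo] / 0.25) / s.lower_tail_rate
        out[mid1] = s.q1 + (u[mid1] - 0.25) * (s.median - s.q1) / 0.25
        out[mid2] = s.median + (u[mid2] - 0.5) * (s.q3 - s.median) / 0.25
        out[hi] = s.q3 - np.log((1.0 - u[hi]) / 0.25) / s.upper_tail_rate
        return out if out.ndim else float(out)

    def point_mass(self, value: float) -> float:
        """Closed-form probability that a draw equals *value* exactly.

        Only flat anchor segments carry mass: 0.25 for each of the
        (q1, median) and (median, q3) intervals that are degenerate at
        *value*; the continuous pieces contribute measure zero.
        """
        s = self.spec
        mass = 0.0
        if s.q1 == s.median == value:
            mass += 0.25
        if s.median == s.q3 == value:
            mass += 0.25
        return mass

    def sample(self, n: int, rng: np.random.Generator):
        """Draw *n* signed offsets (years) by inverse transform."""
        return self.quantile(rng.uniform(np.finfo(float).tiny, 1.0, size=n))


def build_quantile_sampler(spec: TimingSpec) -> QuantileSampler:
    """Construct the quantile-anchored sampler for one condition."""
    return QuantileSampler(spec)


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort."""

    n_participants: int
    specs: tuple[TimingSpec, ...]
    male_fraction: float = 0.64
    index_age_mean: float = 69.8
    index_age_sd: float = 9.9
    index_age_bounds: tuple[float, float] = (35.0, 95.0)
    index_window: tuple[str, str] = ("2000-01-01", "2014-12-31")
    study_end: str = "2024-04-24"
    index_condition: str = INDEX_CONDITION
    duplicate_record_prob: float = 0.3
    self_report_prob: float = 0.1
    invalid_date_prob: float = 0.05
    placeholder_dates: tuple[str, ...] = DEFAULT_PLACEHOLDER_DATES
    sex_stratified_medians: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be non-negative")
        for name in ("male_fraction", "duplicate_record_prob", "self_report_prob", "invalid_date_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} = {p} outside [0, 1]")
        lo, hi = self.index_age_bounds
        if not lo < hi:
            raise ConfigurationError("index_age_bounds must be an increasing pair")

    def spec_for(self, condition: str) -> TimingSpec:
        for s in self.specs:
            if s.condition == condition:
                return s
        raise KeyError(condition)


def _as_timestamp(d) -> pd.Timestamp:
    return pd.Timestamp(d)


def load_config(path: str | Path | None = None, **overrides) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML.

    With no *path*, the packaged default calibration is used: per-condition
    lifetime prevalences and quartile anchors of a heart-failure cohort,
    64/36 male/female split and age at index ~ N(69.8, 9.9²) truncated to
    (35, 95) years.  Keyword *overrides* replace top-level fields.
    """
    if path is None:
        ref = importlib.resources.files("comorbtraj").joinpath("data/default_cohort.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))

    cond = raw.pop("conditions")
    specs = tuple(
        TimingSpec(
            condition=name,
            prevalence=float(v["prevalence"]),
            q1=float(v["q1"]),
            median=float(v["median"]),
            q3=float(v["q3"]),
            lower_tail_rate=float(v.get("lower_tail_rate", DEFAULT_TAIL_RATE)),
            upper_tail_rate=float(v.get("upper_tail_rate", DEFAULT_TAIL_RATE)),
        )
        for name, v in cond.items()
    )
    raw["specs"] = specs
    raw["index_age_bounds"] = tuple(raw.get("index_age_bounds", (35.0, 95.0)))
    raw["index_window"] = tuple(raw.get("index_window", ("2000-01-01", "2014-12-31")))
    raw["placeholder_dates"] = tuple(raw.get("placeholder_dates", DEFAULT_PLACEHOLDER_DATES))
    raw["sex_stratified_medians"] = raw.get("sex_stratified_medians", {}) or {}
    raw.update(overrides)
    return CohortConfig(**raw)


_PARTICIPANT_COLS = ["participant_id", "sex", "birth_year", "birth_month", "death_date", "censor_date"]
_EVENT_COLS = ["participant_id", "condition", "event_date", "source"]
_TRUTH_COLS = ["participant_id", "condition", "true_first_date"]


def _empty_tables():
    participants = pd.DataFrame(columns=_PARTICIPANT_COLS)
    events = pd.DataFrame(columns=_EVENT_COLS)
    truth = pd.DataFrame(columns=_TRUTH_COLS)
    return participants, events, truth


def generate_cohort(config: CohortConfig):
    """Generate (participants, events, truth) tables.

    Every participant receives the index condition; its calendar date is
    drawn uniformly over ``config.index_window`` and the censor date is
    ``config.study_end`` for everyone.  Each comorbidity is present with its
    spec prevalence; when present, its first date is the index date plus a
    sampled offset rounded to whole days.  Offsets are redrawn until the
    date falls inside the observable window (after birth, on or before the
    censor date), so the truth table contains only resolvable dates.

    Every true first occurrence is emitted as one ``primary_care`` event;
    use :func:`corrupt_events` to add realistic noise on top.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if n == 0:
        return _empty_tables()

    study_end = _as_timestamp(config.study_end)
    win_lo, win_hi = (_as_timestamp(d) for d in config.index_window)
    if not win_lo <= win_hi <= study_end:
        raise ConfigurationError("index_window must be ordered and end on/before study_end")

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")

    # truncated-normal age at index by rejection (bounds are several SD out,
    # so acceptance is high)
    lo, hi = config.index_age_bounds
    age = rng.normal(config.index_age_mean, config.index_age_sd, size=n)
    bad = (age < lo) | (age > hi)
    while bad.any():
        age[bad] = rng.normal(config.index_age_mean, config.index_age_sd, size=int(bad.sum()))
        bad = (age < lo) | (age > hi)

    window_days = int((win_hi - win_lo).days)
    index_date = win_lo + pd.to_timedelta(rng.integers(0, window_days + 1, size=n), unit="D")
    birth_date = index_date - pd.to_timedelta(np.round(age * DAYS_PER_YEAR).astype(int), unit="D")

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "birth_year": birth_date.year,
            "birth_month": birth_date.month,
            "death_date": pd.NaT,
            "censor_date": study_end,
        }
    )

    truth_frames = [
        pd.DataFrame(
            {"participant_id": ids, "condition": config.index_condition, "true_first_date": index_date}
        )
    ]

    # analysis-side birth is imputed to the 1st of the birth month; use that
    # as the validity floor so generated dates always survive validation
    birth_floor = pd.to_datetime(
        {"year": participants["birth_year"], "month": participants["birth_month"], "day": 1}
    ).to_numpy()
    index_np = index_date.to_numpy()
    end_np = study_end.to_datetime64()

    for spec in config.specs:
        sampler = QuantileSampler(spec)
        present = rng.random(n) < spec.prevalence
        m = int(present.sum())
        if m == 0:
            continue
        offsets = np.round(sampler.sample(m, rng) * DAYS_PER_YEAR).astype("timedelta64[D]")
        dates = index_np[present] + offsets
        # truncate to the observable window by resampling out-of-range draws
        floor = birth_floor[present]
        for _ in range(1000):
            invalid = (dates <= floor) | (dates > end_np)
            k = int(invalid.sum())
            if k == 0:
                break
            redraws = np.round(sampler.sample(k, rng) * DAYS_PER_YEAR).astype("timedelta64[D]")
            dates[invalid] = index_np[present][invalid] + redraws
        else:  # pragma: no cover - astronomically unlikely under sane configs
            dates = np.clip(dates, floor + np.timedelta64(1, "D"), end_np)
        truth_frames.append(
            pd.DataFrame(
                {"participant_id": ids[present], "condition": spec.condition, "true_first_date": dates}
            )
        )

    truth = pd.concat(truth_frames, ignore_index=True)
    truth = truth.sort_values(["participant_id", "condition"], kind="mergesort").reset_index(drop=True)

    events = truth.rename(columns={"true_first_date": "event_date"}).copy()
    events["source"] = "primary_care"
    events = events[_EVENT_COLS].reset_index(drop=True)
    return participants, events, truth


def corrupt_events(events: pd.DataFrame, truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Layer record noise on a clean event stream.

    Per true occurrence, independently:

    * with ``duplicate_record_prob`` add a ``hospital`` record dated on or
      after the true first date (cross-source duplication);
    * with ``self_report_prob`` add a ``self_report`` record, possibly
      *earlier* than the true date — resolution must ignore it by source,
      not by date;
    * with ``invalid_date_prob`` add a record carrying a placeholder
      sentinel, a pre-birth date, or a post-censor date.

    The truth table is untouched: a correct resolver recovers it exactly
    from the corrupted stream.  Deterministic given ``config.seed``.
    """
    if len(truth) == 0:
        return events.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 0xC0]))
    study_end = _as_timestamp(config.study_end).to_datetime64()
    placeholders = np.array([_as_timestamp(d).to_datetime64() for d in config.placeholder_dates])

    t = truth.reset_index(drop=True)
    dates = pd.to_datetime(t["true_first_date"]).to_numpy()
    n = len(t)
    extra = []

    dup = rng.random(n) < config.duplicate_record_prob
    if dup.any():
        lag = rng.integers(0, 3 * 365, size=int(dup.sum())).astype("timedelta64[D]")
        dup_dates = np.minimum(dates[dup] + lag, study_end)
        extra.append(
            pd.DataFrame(
                {
                    "participant_id": t.loc[dup, "participant_id"].to_numpy(),
                    "condition": t.loc[dup, "condition"].to_numpy(),
                    "event_date": dup_dates,
                    "source": "hospital",
                }
            )
        )

    sr = rng.random(n) < config.self_report_prob
    if sr.any():
        lead = rng.integers(0, 2 * 365, size=int(sr.sum())).astype("timedelta64[D]")
        extra.append(
            pd.DataFrame(
                {
                    "participant_id": t.loc[sr, "participant_id"].to_numpy(),
                    "condition": t.loc[sr, "condition"].to_numpy(),
                    "event_date": dates[sr] - lead,
                    "source": "self_report",
                }
            )
        )

    inv = rng.random(n) < config.invalid_date_prob
    if inv.any():
        k = int(inv.sum())
        kind = rng.integers(0, 3, size=k)
        bad_dates = np.empty(k, dtype="datetime64[ns]")
        # placeholder sentinel
        bad_dates[kind == 0] = placeholders[rng.integers(0, len(placeholders), size=int((kind == 0).sum()))]
        # far before any plausible birth date
        pre = kind == 1
        bad_dates[pre] = np.datetime64("1850-01-01") + rng.integers(
            0, 3650, size=int(pre.sum())
        ).astype("timedelta64[D]")
        # after the censor date
        post = kind == 2
        bad_dates[post] = study_end + rng.integers(1, 3650, size=int(post.sum())).astype(
            "timedelta64[D]"
        )
        extra.append(
            pd.DataFrame(
                {
                    "participant_id": t.loc[inv, "participant_id"].to_numpy(),
                    "condition": t.loc[inv, "condition"].to_numpy(),
                    "event_date": bad_dates,
                    "source": "hospital",
                }
            )
        )

    if not extra:
        return events.copy()
    out = pd.concat([events] + extra, ignore_index=True)
    out["event_date"] = pd.to_datetime(out["event_date"])
    out = out.sort_values(
        ["participant_id", "condition", "event_date", "source"], kind="mergesort"
    ).reset_index(drop=True)
    return out
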