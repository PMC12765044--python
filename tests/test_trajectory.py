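"""Index-relative trajectory statistics."""

import numpy as np
import pandas as pd
import pytest

import comorbtraj as ct
from comorbtraj.trajectory import NONE_LABEL, default_accrual_grid

from conftest import make_occurrences


class TestRelativeTime:
    @pytest.mark.parametrize(
        "occ,idx,expected",
        [
            ("2010-01-01", "2010-01-01", 0.0),
            ("2000-01-01", "2010-01-01", -3653 / 365.25),  # includes 3 leap days
            ("2010-01-02", "2010-01-01", 1 / 365.25),
        ],
    )
    def test_day_count_convention(self, occ, idx, expected):
        assert ct.relative_time_years(occ, idx) == pytest.approx(expected, abs=1e-12)


class TestSequencePosition:
    def test_no_comorbidities_is_first(self):
        occ = make_occurrences([("P1", "heart_failure", "2010-01-01")])
        assert ct.sequence_position(occ, "heart_failure") == 1

    def test_same_day_diagnoses_are_not_predecessors(self):
        occ = make_occurrences(
            [("P1", "heart_failure", "2010-01-01")]
            + [("P1", c, d) for c, d in [
                ("stroke", "2000-01-01"), ("diabetes", "2005-01-01"), ("asthma", "2009-12-31"),
                ("anaemia", "2010-01-01"), ("obesity", "2010-01-01"),
                ("dementia", "2015-01-01"),
            ]]
        )
        assert ct.sequence_position(occ, "heart_failure") == 4

    def test_missing_index_is_contract_violation(self):
        occ = make_occurrences([("P1", "stroke", "2000-01-01")])
        with pytest.raises(ValueError):
            ct.sequence_position(occ, "heart_failure")

    def test_matches_brute_force_rank_on_random_cases(self, rng):
        """1,000 random mini-histories: position equals the 1-based rank of
        the index date in the sorted diagnosis dates (strict predecessors)."""
        conditions = list(ct.COMORBIDITIES)
        base = pd.Timestamp("2010-01-01")
        for _ in range(1000):
            k = int(rng.integers(0, 8))
            chosen = rng.choice(conditions, size=k, replace=False)
            offsets = rng.integers(-400, 400, size=k)
            rows = [("P1", "heart_failure", base)] + [
                ("P1", c, base + pd.Timedelta(days=int(o))) for c, o in zip(chosen, offsets)
            ]
            occ = make_occurrences([(p, c, d) for p, c, d in rows])
            brute = 1 + sum(1 for _, c, d in rows[1:] if d < base)
            assert ct.sequence_position(occ, "heart_failure") == brute

    def test_vectorized_path_agrees_with_negative_time_count(self, small_cohort):
        """Independent cross-check: 1 + (# strictly negative relative times)."""
        pos = ct.sequence_positions(small_cohort)
        rel = ct.relative_times(small_cohort)
        neg = (
            rel[rel["years_from_index"] < 0].groupby("participant_id").size()
        ).reindex(small_cohort.participants["participant_id"], fill_value=0)
        assert (pos == neg + 1).all()

    def test_removing_same_day_records_changes_no_position(self, small_cohort):
        pos = ct.sequence_positions(small_cohort)
        rel = ct.relative_times(small_cohort)
        sync = rel[rel["years_from_index"] == 0]
        keep = ~small_cohort.occurrences.set_index(["participant_id", "condition"]).index.isin(
            sync.set_index(["participant_id", "condition"]).index
        )
        slim = ct.Cohort(
            small_cohort.participants,
            small_cohort.occurrences[keep].reset_index(drop=True),
            small_cohort.index_condition,
            small_cohort.fraction,
        )
        assert (ct.sequence_positions(slim) == pos).all()


class TestTimingSummary:
    def test_single_value_degenerates(self):
        rel = pd.DataFrame({"participant_id": ["P1"], "condition": ["stroke"], "years_from_index": [2.5]})
        s = ct.timing_summary(rel, "stroke")
        assert s.median == s.q1 == s.q3 == 2.5 and s.n == 1

    def test_linear_interpolation_hand_case(self):
        """{−4, −2, 0, 0, 1}: quartile positions fall on order statistics."""
        rel = pd.DataFrame(
            {"participant_id": list("abcde"), "condition": "x",
             "years_from_index": [-4.0, -2.0, 0.0, 0.0, 1.0]}
        )
        s = ct.timing_summary(rel, "x")
        assert (s.median, s.q1, s.q3) == (0.0, -2.0, 0.0)

    def test_zero_observations_omitted_with_warning(self, caplog):
        rel = pd.DataFrame(columns=["participant_id", "condition", "years_from_index"])
        assert ct.timing_summary(rel, "stroke") is None

    @pytest.mark.parametrize(
        "q1,q3,expected", [(-2.4, 0.0, 2.4), (-14.4, 0.0, 14.4), (-1.0, -1.0, 0.0)]
    )
    def test_iqr_width(self, q1, q3, expected):
        s = ct.TimingSummary("x", n=10, median=(q1 + q3) / 2, q1=q1, q3=q3)
        assert ct.iqr_width(s) == pytest.approx(expected)

    def test_sampler_median_recovered(self, default_config, rng):
        """1e5 draws from the osteoarthritis sampler give median ≈ −6.9."""
        spec = default_config.spec_for("osteoarthritis")
        draws = ct.build_quantile_sampler(spec).sample(100_000, rng)
        rel = pd.DataFrame(
            {"participant_id": np.arange(draws.size), "condition": "osteoarthritis",
             "years_from_index": draws}
        )
        s = ct.timing_summary(rel, "osteoarthritis")
        assert s.median == pytest.approx(-6.9, abs=0.1)


class TestAccrualCurve:
    def test_single_participant_step(self):
        rel = pd.DataFrame(
            {"participant_id": ["P1"], "condition": ["stroke"], "years_from_index": [-5.0]}
        )
        fup = pd.Series([10.0], index=["P1"])
        c = ct.accrual_curve(rel, fup, grid=np.array([-10.0, -5.0, 0.0, 5.0]))
        assert list(c.mean_count) == [0.0, 1.0, 1.0, 1.0]
        assert np.isnan(c.ci_low).all()  # single participant: CI undefined

    def test_at_risk_denominator_respects_follow_up(self):
        """With follow-ups of 2 and 10 years, only the long-follow-up
        participant contributes at t = +5."""
        rel = pd.DataFrame(
            {"participant_id": ["P1", "P2"], "condition": ["stroke", "stroke"],
             "years_from_index": [-1.0, 4.0]}
        )
        fup = pd.Series([2.0, 10.0], index=["P1", "P2"])
        c = ct.accrual_curve(rel, fup, grid=np.array([-2.0, 0.0, 1.0, 5.0]))
        assert list(c.n_at_risk) == [2, 2, 2, 1]
        assert c.mean_count[1] == pytest.approx(0.5)  # P1's stroke only
        assert c.mean_count[3] == pytest.approx(1.0)  # P2 alone, 1 comorbidity

    def test_monotone_before_index_and_limit_is_mean_count(self, small_cohort):
        rel = ct.relative_times(small_cohort)
        fup = pd.Series(np.inf, index=small_cohort.participants["participant_id"])
        grid = default_accrual_grid(-30, 40, 0.5)
        c = ct.accrual_curve(rel, fup, grid=grid)
        pre = c.mean_count[grid <= 0]
        assert np.all(np.diff(pre) >= 0)
        per_person = rel.groupby("participant_id").size().reindex(
            small_cohort.participants["participant_id"], fill_value=0
        )
        assert c.mean_count[-1] == pytest.approx(per_person.mean())
        assert np.all((c.ci_low <= c.mean_count + 1e-12) & (c.mean_count <= c.ci_high + 1e-12))

    def test_empty_cohort_empty_curve(self):
        rel = pd.DataFrame(columns=["participant_id", "condition", "years_from_index"])
        c = ct.accrual_curve(rel, pd.Series(dtype=float), grid=np.array([0.0, 1.0]))
        assert (c.n_at_risk == 0).all()

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            ct.accrual_curve(
                pd.DataFrame(columns=["participant_id", "condition", "years_from_index"]),
                pd.Series([1.0], index=["P1"]),
                grid=np.array([1.0, 0.0]),
            )


class TestAdjacentDiagnoses:
    def test_before_after_synchronous_basic(self):
        occ = make_occurrences(
            [("P1", "heart_failure", "2010-01-01"), ("P1", "stroke", "2007-01-01"),
             ("P1", "diabetes", "2009-01-01"), ("P1", "cancer", "2012-01-01")]
        )
        r = ct.adjacent_diagnoses(occ, "heart_failure")
        assert (r.before, r.after, r.synchronous) == ("diabetes", "cancer", ())

    def test_no_comorbidities_is_countable_none(self):
        occ = make_occurrences([("P1", "heart_failure", "2010-01-01")])
        r = ct.adjacent_diagnoses(occ, "heart_failure")
        assert r.before is None and r.after is None and r.synchronous == ()

    def test_date_tie_broken_by_priority_order(self):
        # osteoarthritis comes after dementia in the fixed priority list
        occ = make_occurrences(
            [("P1", "heart_failure", "2010-01-01"),
             ("P1", "osteoarthritis", "2009-01-01"), ("P1", "dementia", "2009-01-01")]
        )
        assert ct.adjacent_diagnoses(occ, "heart_failure").before == "dementia"

    def test_vectorized_transitions_agree_with_scalar(self, small_cohort):
        trans = ct.transitions(small_cohort).set_index("participant_id")
        occ_all = pd.concat(
            [
                small_cohort.occurrences,
                small_cohort.participants[["participant_id", "index_date"]]
                .rename(columns={"index_date": "first_date"})
                .assign(condition=small_cohort.index_condition),
            ],
            ignore_index=True,
        )
        sample = small_cohort.participants["participant_id"].iloc[::37]
        for pid in sample:
            rows = occ_all[occ_all["participant_id"] == pid]
            r = ct.adjacent_diagnoses(rows, small_cohort.index_condition)
            assert (r.before or NONE_LABEL) == trans.loc[pid, "before"]
            assert (r.after or NONE_LABEL) == trans.loc[pid, "after"]
            assert r.synchronous == trans.loc[pid, "synchronous"]


class TestTransitionTable:
    def test_all_none_cohort(self):
        records = pd.DataFrame(
            {"participant_id": ["P1", "P2"], "before": [NONE_LABEL] * 2,
             "synchronous": [(), ()], "after": [NONE_LABEL] * 2}
        )
        table = ct.transition_table(records).set_index("condition")
        assert table.loc[NONE_LABEL, "before_pct"] == 100.0
        assert table.loc[NONE_LABEL, "synchronous_pct"] == 100.0
        assert table.loc[NONE_LABEL, "after_pct"] == 100.0

    def test_hand_built_five_participant_tally(self):
        records = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(5)],
                "before": ["stroke", "stroke", "cancer", NONE_LABEL, NONE_LABEL],
                "synchronous": [("anaemia", "copd"), (), ("anaemia",), (), ()],
                "after": ["dementia", NONE_LABEL, NONE_LABEL, "dementia", "cancer"],
            }
        )
        t = ct.transition_table(records).set_index("condition")
        assert t.loc["stroke", "before_n"] == 2 and t.loc["cancer", "before_n"] == 1
        assert t.loc[NONE_LABEL, "before_n"] == 2
        assert t.loc["anaemia", "synchronous_n"] == 2 and t.loc["copd", "synchronous_n"] == 1
        assert t.loc[NONE_LABEL, "synchronous_n"] == 3
        assert t.loc["dementia", "after_n"] == 2 and t.loc[NONE_LABEL, "after_n"] == 2
        assert t.loc["stroke", "before_pct"] == pytest.approx(40.0)

    def test_column_conservation_on_synthetic_cohort(self, small_cohort):
        trans = ct.transitions(small_cohort)
        t = ct.transition_table(trans)
        n = small_cohort.size
        assert t["before_n"].sum() == n
        assert t["after_n"].sum() == n
        sync_total = t.set_index("condition").drop(NONE_LABEL)["synchronous_n"].sum()
        assert sync_total == trans["synchronous"].apply(len).sum()

    def test_sankey_links_exclude_synchronous_and_conserve_cohort(self, small_cohort):
        trans = ct.transitions(small_cohort)
        links = ct.sankey_links(trans)
        assert sum(l["value"] for l in links) == small_cohort.size
        assert all(l["source"].startswith("before:") for l in links)
        assert not any("synchronous" in l["source"] + l["target"] for l in links)
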