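"""Statistics tests: category tabulation at printed precision, Fisher's
exact test against an independent implementation, Mann–Whitney U against
brute-force enumeration, and timing summaries."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from plancheck import datasets
from plancheck.audit import (
    ALL_CATEGORIES,
    ContingencyTable2x2,
    IssueRecord,
    Period,
    TimeRecord,
    build_table2,
    build_table3,
    categorize,
    contingency_from_records,
    fisher_exact_2x2,
    mann_whitney_u,
    round_half_up,
    summarize_times,
    summary_ratios,
)


class TestCategorize:
    def test_bundled_audit_subtotals(self):
        """The bundled two-period audit: 150/50 issues (75.00%/25.00%)
        before deployment, 114/13 (89.76%/10.24%) after."""
        table = categorize(datasets.issue_records_from_counts())
        assert table.loc["Unrelated subtotal", "pre_count"] == 150
        assert table.loc["Related subtotal", "pre_count"] == 50
        assert table.loc["Unrelated subtotal", "pre_pct"] == 75.00
        assert table.loc["Related subtotal", "pre_pct"] == 25.00
        assert table.loc["Unrelated subtotal", "with_count"] == 114
        assert table.loc["Related subtotal", "with_count"] == 13
        assert table.loc["Unrelated subtotal", "with_pct"] == 89.76
        assert table.loc["Related subtotal", "with_pct"] == 10.24
        assert table.loc["Grand total", "pre_count"] == 200
        assert table.loc["Grand total", "with_count"] == 127

    def test_category_percentages_at_printed_precision(self):
        table = categorize(datasets.issue_records_from_counts())
        assert table.loc["Missing/incorrect contours or Booleans", "pre_pct"] == 10.5
        assert (
            table.loc["Missing/incorrect documentation, billing, database logs", "with_pct"]
            == 38.6
        )
        assert table.loc["Completion status of non-clinical courses", "pre_pct"] == 8.5

    def test_rounded_percentages_sum_to_100(self):
        table = categorize(datasets.issue_records_from_counts())
        cats = table.iloc[:17]
        for col in ("pre_pct", "with_pct"):
            assert cats[col].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_records_render_dashes(self):
        table = categorize([])
        assert table["pre_count"].sum() == 0
        assert math.isnan(table.loc["Grand total", "pre_pct"])
        assert "—" in build_table2([])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown issue category"):
            IssueRecord(period=Period.PRE, category="Wrong label")

    def test_pct_related_derived_from_taxonomy(self):
        rec = IssueRecord(period=Period.PRE, category="Incorrect grid size")
        assert rec.pct_related
        rec = IssueRecord(period=Period.PRE, category="Prescription problems")
        assert not rec.pct_related


class TestFisher:
    def test_headline_table_significant(self):
        """The bundled audit's 2x2 table is significant below 0.001."""
        table = contingency_from_records(datasets.issue_records_from_counts())
        assert (table.a, table.b, table.c, table.d) == (150, 50, 114, 13)
        p = fisher_exact_2x2(table)
        assert p < 0.001

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2((1, 1, 1, 1)) == pytest.approx(1.0)

    def test_small_table_equals_hand_enumeration(self):
        """(3,1|1,3) with margins (4,4)/(4,4): of the 5 possible tables the
        ones at most as probable as observed carry 34/70 of the mass."""
        assert fisher_exact_2x2((3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2((0, 0, 3, 4)) == 1.0

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_independent_implementation(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        ours = fisher_exact_2x2((a, b, c, d))
        _, ref = scipy_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariance_and_range(self, a, b, c, d):
        """p in (0, 1]; invariant under simultaneous row and column swap."""
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        p = fisher_exact_2x2((a, b, c, d))
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_exact_2x2((d, c, b, a)))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_identical_samples_centre_of_distribution(self):
        res = mann_whitney_u([3.0, 1.0, 2.0], [2.0, 1.0, 3.0])
        assert res.U == pytest.approx(res.n1 * res.n2 / 2)
        assert abs(res.z) < 1e-9
        assert res.p_two_sided == pytest.approx(1.0)

    def test_fully_separated_samples_exact_p(self):
        """x={1,2,3} below y={4,5,6}: U=0 and the exact two-sided p is
        2/20 = 0.1 over all C(6,3) labelings."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p_exact == pytest.approx(0.1)

    def test_swap_antisymmetry(self):
        x, y = [1.0, 5.0, 3.0, 8.0], [2.0, 9.0, 4.0]
        fwd = mann_whitney_u(x, y)
        rev = mann_whitney_u(y, x)
        assert fwd.U + rev.U == pytest.approx(len(x) * len(y))
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)
        assert fwd.p_exact == pytest.approx(rev.p_exact)

    def test_all_tied_defined_result(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.U == pytest.approx(3.0)
        assert res.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        x=st.lists(st.integers(0, 12), min_size=1, max_size=7),
        y=st.lists(st.integers(0, 12), min_size=1, max_size=7),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_exact_p_matches_brute_force(self, x, y):
        """The DP enumeration equals a literal loop over all C(n, n1)
        labelings, including ties."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied draws are legitimate here
            res = mann_whitney_u(x, y)
        pooled = np.array(x + y, dtype=float)
        ranks = scipy_stats.rankdata(pooled)
        n1 = len(x)
        obs = ranks[:n1].sum()
        sums = np.array(
            [sum(ranks[i] for i in idx) for idx in itertools.combinations(range(len(pooled)), n1)]
        )
        le = np.mean(sums <= obs + 1e-9)
        ge = np.mean(sums >= obs - 1e-9)
        brute = min(1.0, 2.0 * min(le, ge))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert res.p_exact == pytest.approx(brute)

    def test_matches_scipy_asymptotic_with_ties(self):
        x = [5.0, 7.0, 7.0, 9.0, 12.0, 12.0, 15.0]
        y = [6.0, 7.0, 10.0, 12.0, 14.0, 18.0, 20.0, 21.0]
        res = mann_whitney_u(x, y)
        ref = scipy_stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


class TestTimingSummary:
    @staticmethod
    def _records():
        recs = []
        for minutes in (40.0, 50.0, 60.0):
            recs.append(TimeRecord(Period.PRE, "A", minutes))
            recs.append(TimeRecord(Period.WITH, "A", minutes - 10.0))
        recs.append(TimeRecord(Period.PRE, "G", 39.0))  # PRE only
        recs.append(TimeRecord(Period.WITH, "J", 30.5))  # WITH only
        return recs

    def test_ratios_from_unrounded_summaries(self):
        table = summarize_times(self._records())
        assert table.loc["A", "mean_ratio"] == pytest.approx(0.8)
        assert table.loc["A", "median_ratio"] == pytest.approx(0.8)

    def test_single_period_person_has_blank_ratios(self):
        table = summarize_times(self._records())
        assert math.isnan(table.loc["G", "mean_ratio"])
        assert math.isnan(table.loc["J", "median_ratio"])
        assert "N/A" in build_table3(self._records())

    def test_equal_values_ratio_one(self):
        recs = [TimeRecord(Period.PRE, "A", 45.0), TimeRecord(Period.WITH, "A", 45.0)]
        table = summarize_times(recs)
        assert table.loc["A", "mean_ratio"] == 1.00

    def test_published_overall_summaries_round_to_printed_ratios(self):
        """Means 49.4 -> 39.3 and medians 45 -> 35 give ratios 0.80 / 0.78
        and a 20% mean decrease."""
        summary = datasets.load_timing_summary().loc["Overall"]
        ratios = summary_ratios(
            summary["pre_mean"], summary["pre_median"],
            summary["with_mean"], summary["with_median"],
        )
        assert ratios["mean_ratio"] == 0.80
        assert ratios["median_ratio"] == 0.78
        assert ratios["mean_decrease_pct"] == 20

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(10.235, 2) == 10.24
        assert round_half_up(2.5, 0) == 3.0

    def test_nonpositive_minutes_rejected(self):
        with pytest.raises(ValueError):
            TimeRecord(Period.PRE, "A", 0.0)


class TestRenderedTables:
    def test_table2_text_layout(self):
        text = build_table2(datasets.issue_records_from_counts())
        assert "Un-related to automated checks:" in text
        assert "Related to automated checks:" in text
        assert "Grand total" in text

    def test_table2_csv_round_trips(self):
        import io

        import pandas as pd

        csv = build_table2(datasets.issue_records_from_counts(), fmt="csv")
        df = pd.read_csv(io.StringIO(csv), index_col=0)
        assert df.loc["Grand total", "pre_count"] == 200

    def test_single_category_table(self):
        recs = [IssueRecord(Period.PRE, ALL_CATEGORIES[0])]
        text = build_table2(recs)
        assert "100.0%" in text
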