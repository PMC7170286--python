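"""Audit statistics for before/after deployment comparisons.

A deployment audit records, for two periods (``PRE`` before the automated
tool entered clinical use, ``WITH`` after), every issue a human plan
checker found — classified into a fixed 17-category taxonomy, of which 8
categories correspond to checks the tool automates — and the duration of
each chart check.  This module computes the summary tables and the two
hypothesis tests from first principles:

* the category table with per-period counts and percentages, and the
  related/unrelated subtotals;
* Fisher's exact test (two-sided, minimum-likelihood convention) on the
  2x2 period x {unrelated, related} table, in exact integer arithmetic;
* the Mann–Whitney U test on per-check times, with midranks for ties, a
  tie-corrected normal approximation with optional continuity correction,
  and an exact permutation p-value by dynamic-programming enumeration for
  small samples.

The printed-precision conventions (1 decimal for category percentages, 2
for subtotals, half-up rounding) are preserved so rendered tables are
byte-comparable against institutional reports.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "Period",
    "IssueRecord",
    "TimeRecord",
    "ContingencyTable2x2",
    "UNRELATED_CATEGORIES",
    "RELATED_CATEGORIES",
    "ALL_CATEGORIES",
    "round_half_up",
    "categorize",
    "contingency_from_records",
    "fisher_exact_2x2",
    "MannWhitneyResult",
    "mann_whitney_u",
    "summarize_times",
    "summary_ratios",
    "build_table2",
    "build_table3",
]


class Period(str, enum.Enum):
    PRE = "PRE"
    WITH = "WITH"


#: Issue taxonomy: categories the automated tool is not designed to catch...
UNRELATED_CATEGORIES = (
    "Missing/incorrect contours or Booleans",
    "Missing/incorrect documentation, billing, database logs",
    "Prescription problems",
    "Plan quality: DVH, isodose lines, beam arrangement, missing flash",
    "R&V details: treatment time, imaging templates, scheduling, carepaths, breakpoints",
    "DRR quality, window/level",
    "Treatment field technical parameters (names, MLC, intensities, jaws, etc.)",
    "Setup field technical parameters (angles, names, etc.)",
    "Miscellaneous",
)

#: ... and categories that map directly onto automated checkers.
RELATED_CATEGORIES = (
    "Completion status of non-clinical courses",
    "DRR overlays",
    "Treatment field technical parameters: bolus, couch coordinates",
    "Setup field technical parameters: imager position",
    "Reference points: missing or incorrect contributions",
    "Incorrect grid size",
    "Course/plan does not follow naming conventions",
    "Incorrect tolerance tables",
)

ALL_CATEGORIES = UNRELATED_CATEGORIES + RELATED_CATEGORIES


@dataclass(frozen=True)
class IssueRecord:
    """One issue recorded by a human plan checker."""

    period: Period
    category: str
    checker_person_id: str = ""

    def __post_init__(self):
        if self.category not in ALL_CATEGORIES:
            raise ValueError(f"unknown issue category: {self.category!r}")

    @property
    def pct_related(self) -> bool:
        """True iff the category maps onto an automated checker."""
        return self.category in RELATED_CATEGORIES


@dataclass(frozen=True)
class TimeRecord:
    """Duration of one chart check, less breaks and interruptions."""

    period: Period
    checker_person_id: str
    minutes: float

    def __post_init__(self):
        if not self.minutes > 0:
            raise ValueError("minutes must be positive")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention of printed clinical tables;
    Python's builtin ``round`` is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Category table
# ---------------------------------------------------------------------------


def categorize(records: Iterable[IssueRecord]) -> pd.DataFrame:
    """Tabulate issues per category and period.

    Returns a DataFrame indexed by category label (in taxonomy order) with
    three trailing summary rows — ``Unrelated subtotal``, ``Related
    subtotal`` and ``Grand total`` — and columns ``section``, ``pre_count``,
    ``pre_pct``, ``with_count``, ``with_pct``.  Percentages are of the
    period's grand total, rounded half-up to 1 decimal for categories and 2
    decimals for subtotals; they are NaN when the period has no records.
    """
    counts = {p: dict.fromkeys(ALL_CATEGORIES, 0) for p in Period}
    for rec in records:
        counts[rec.period][rec.category] += 1

    totals = {p: sum(counts[p].values()) for p in Period}

    def pct(count: int, period: Period, ndigits: int) -> float:
        if totals[period] == 0:
            return float("nan")
        return round_half_up(100.0 * count / totals[period], ndigits)

    rows = []
    for cat in ALL_CATEGORIES:
        section = "related" if cat in RELATED_CATEGORIES else "unrelated"
        rows.append(
            {
                "category": cat,
                "section": section,
                "pre_count": counts[Period.PRE][cat],
                "pre_pct": pct(counts[Period.PRE][cat], Period.PRE, 1),
                "with_count": counts[Period.WITH][cat],
                "with_pct": pct(counts[Period.WITH][cat], Period.WITH, 1),
            }
        )
    for label, section, cats in (
        ("Unrelated subtotal", "unrelated", UNRELATED_CATEGORIES),
        ("Related subtotal", "related", RELATED_CATEGORIES),
    ):
        sub = {p: sum(counts[p][c] for c in cats) for p in Period}
        rows.append(
            {
                "category": label,
                "section": section,
                "pre_count": sub[Period.PRE],
                "pre_pct": pct(sub[Period.PRE], Period.PRE, 2),
                "with_count": sub[Period.WITH],
                "with_pct": pct(sub[Period.WITH], Period.WITH, 2),
            }
        )
    rows.append(
        {
            "category": "Grand total",
            "section": "total",
            "pre_count": totals[Period.PRE],
            "pre_pct": pct(totals[Period.PRE], Period.PRE, 2),
            "with_count": totals[Period.WITH],
            "with_pct": pct(totals[Period.WITH], Period.WITH, 2),
        }
    )
    return pd.DataFrame(rows).set_index("category")


def contingency_from_records(records: Iterable[IssueRecord]) -> "ContingencyTable2x2":
    """2x2 table of period (rows: PRE, WITH) x relatedness (cols: unrelated,
    related)."""
    a = b = c = d = 0
    for rec in records:
        if rec.period is Period.PRE:
            if rec.pct_related:
                b += 1
            else:
                a += 1
        else:
            if rec.pct_related:
                d += 1
            else:
                c += 1
    return ContingencyTable2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[int]) -> float:
    """Two-sided Fisher's exact test by the minimum-likelihood convention.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed that of the
    observed table.  All arithmetic is on exact integers (binomial
    coefficients), so there is no cancellation error even for margins in
    the thousands; the single final division produces the float p.

    A degenerate table (a row or column of zeros) carries no information
    and returns ``p = 1.0`` with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; Fisher p defined as 1.0", stacklevel=2)
        return 1.0
    observed = math.comb(r1, a) * math.comb(r2, c)
    numerator = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        ways = math.comb(r1, x) * math.comb(r2, c1 - x)
        if ways <= observed:
            numerator += ways
    return numerator / math.comb(n, c1)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  #: U statistic of the first sample
    z: float  #: tie-corrected normal deviate
    p_two_sided: float  #: two-sided p from the normal approximation
    p_exact: Optional[float]  #: exact permutation p (small samples only)
    n1: int
    n2: int


def _exact_mwu_p(ranks: np.ndarray, n1: int, observed_sum: float) -> float:
    """Exact two-sided permutation p for the rank sum of the first sample.

    Midranks are half-integers, so doubling them gives integers and the
    null distribution of the doubled rank sum over all C(n, n1) subsets can
    be counted exactly with a subset-sum dynamic program; no sampling, no
    floats until the final division.
    """
    doubled = np.rint(2 * ranks).astype(int)
    # dp[k] maps doubled-rank-sum -> number of k-subsets achieving it
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0] = {0: 1}
    for value in doubled:
        for k in range(min(n1, len(doubled)), 0, -1):
            prev = dp[k - 1]
            cur = dp[k]
            for s, ways in prev.items():
                cur[s + value] = cur.get(s + value, 0) + ways
    dist = dp[n1]
    total = sum(dist.values())
    target = int(round(2 * observed_sum))
    le = sum(w for s, w in dist.items() if s <= target)
    ge = sum(w for s, w in dist.items() if s >= target)
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    continuity: bool = True,
    exact_limit: int = 400,
) -> MannWhitneyResult:
    """Mann–Whitney U test that ``x`` and ``y`` come from the same
    distribution.

    U is computed from rank sums with midranks assigned to ties.  The
    normal deviate uses the tie-corrected variance

        sigma^2 = (n1 n2 / 12) [ (n+1) - sum(t^3 - t) / (n (n-1)) ]

    with a 0.5 continuity correction toward the mean by default (the
    correction is a convention, not a fact about the data, so it is
    exposed as a switch).  When ``n1 * n2 <= exact_limit`` an exact
    conditional permutation p-value is also computed by enumeration and
    reported alongside; for all-tied samples (sigma = 0) the defined
    result is ``U = n1 n2 / 2, p = 1`` with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rank_sum = float(ranks[:n1].sum())
    U = rank_sum - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var_u = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    p_exact = None
    if n1 * n2 <= exact_limit:
        p_exact = _exact_mwu_p(ranks, n1, rank_sum)

    if var_u <= 0:
        warnings.warn("all observations tied; Mann-Whitney p defined as 1.0", stacklevel=2)
        return MannWhitneyResult(U=mean_u, z=0.0, p_two_sided=1.0, p_exact=p_exact, n1=n1, n2=n2)

    diff = U - mean_u
    if continuity and diff != 0:
        diff = diff - 0.5 * np.sign(diff)
    z = diff / math.sqrt(var_u)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return MannWhitneyResult(U=U, z=z, p_two_sided=p, p_exact=p_exact, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Timing summaries
# ---------------------------------------------------------------------------


def _ratio(with_value: float, pre_value: float) -> float:
    return round_half_up(with_value / pre_value, 2)


def summarize_times(records: Iterable[TimeRecord]) -> pd.DataFrame:
    """Per-person and overall timing summary with WITH/PRE ratios.

    Columns: ``pre_n, pre_mean, pre_median, with_n, with_mean, with_median,
    mean_ratio, median_ratio``; the last row is ``Overall``.  A person
    present in only one period gets NaN ratios.  Ratios are computed from
    the unrounded means/medians and rounded half-up to 2 decimals.
    """
    df = pd.DataFrame(
        [(r.period.value, r.checker_person_id, r.minutes) for r in records],
        columns=["period", "person", "minutes"],
    )
    persons = sorted(df["person"].unique())
    rows = []
    for person in persons + ["Overall"]:
        sub = df if person == "Overall" else df[df["person"] == person]
        row: dict = {"person": person}
        for period, tag in (("PRE", "pre"), ("WITH", "with")):
            vals = sub.loc[sub["period"] == period, "minutes"]
            row[f"{tag}_n"] = int(len(vals))
            row[f"{tag}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{tag}_median"] = float(vals.median()) if len(vals) else float("nan")
        if row["pre_n"] and row["with_n"]:
            row["mean_ratio"] = _ratio(row["with_mean"], row["pre_mean"])
            row["median_ratio"] = _ratio(row["with_median"], row["pre_median"])
        else:
            row["mean_ratio"] = float("nan")
            row["median_ratio"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("person")


def summary_ratios(
    pre_mean: float, pre_median: float, with_mean: float, with_median: float
) -> dict[str, float]:
    """WITH/PRE ratios (and the mean percentage decrease) from already
    summarized timing figures, with the printed rounding conventions."""
    return {
        "mean_ratio": _ratio(with_mean, pre_mean),
        "median_ratio": _ratio(with_median, pre_median),
        "mean_decrease_pct": round_half_up(100.0 * (1.0 - with_mean / pre_mean), 0),
    }


# ---------------------------------------------------------------------------
# Rendered tables
# ---------------------------------------------------------------------------


def _fmt_pct(value: float) -> str:
    return "—" if isinstance(value, float) and math.isnan(value) else f"{value}%"


def build_table2(records: Iterable[IssueRecord], fmt: str = "text") -> str:
    """Render the issue-category table (counts and percentages per period)."""
    table = categorize(records)
    if fmt == "csv":
        return table.to_csv()
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    width = max(len(i) for i in table.index) + 2
    lines = [
        f"{'Category':<{width}}{'# Pre':>7}{'% Pre':>9}{'# With':>8}{'% With':>9}"
    ]
    section_headers = {
        "unrelated": "Un-related to automated checks:",
        "related": "Related to automated checks:",
    }
    last_section = None
    for label, row in table.iterrows():
        if row["section"] in section_headers and row["section"] != last_section:
            lines.append(section_headers[row["section"]])
            last_section = row["section"]
        lines.append(
            f"{label:<{width}}{row['pre_count']:>7}{_fmt_pct(row['pre_pct']):>9}"
            f"{row['with_count']:>8}{_fmt_pct(row['with_pct']):>9}"
        )
    return "\n".join(lines) + "\n"


def build_table3(records: Iterable[TimeRecord], fmt: str = "text") -> str:
    """Render the per-person timing table with WITH/PRE ratios."""
    table = summarize_times(records)
    if fmt == "csv":
        return table.to_csv()
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")

    def num(v, nd=1):
        return "N/A" if isinstance(v, float) and math.isnan(v) else f"{round_half_up(v, nd):g}"

    lines = [
        f"{'Checker':<10}{'n pre':>6}{'mean':>7}{'med':>6}{'n with':>8}{'mean':>7}"
        f"{'med':>6}{'r-mean':>8}{'r-med':>7}"
    ]
    for person, row in table.iterrows():
        lines.append(
            f"{person:<10}{row['pre_n']:>6}{num(row['pre_mean']):>7}{num(row['pre_median']):>6}"
            f"{row['with_n']:>8}{num(row['with_mean']):>7}{num(row['with_median']):>6}"
            f"{num(row['mean_ratio'], 2):>8}{num(row['median_ratio'], 2):>7}"
        )
    return "\n".join(lines) + "\n"
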