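"""Bundled example audit dataset.

A two-period audit of initial chart checks at a large radiotherapy clinic:
per-category issue counts (187 checks / 200 issues before the automated
tool entered clinical use; 186 checks / 127 issues after) and per-person
timing summaries for ten plan checkers.  Only the published summaries are
bundled — the raw per-check durations were never released, which is why
the per-person significance tests cannot be recomputed from this dataset
(see ``docs/methods.md``).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .audit import ALL_CATEGORIES, IssueRecord, Period

__all__ = [
    "load_issue_counts",
    "load_timing_summary",
    "issue_records_from_counts",
    "PRE_CHECKS",
    "WITH_CHECKS",
]

#: number of chart checks performed in each audit period
PRE_CHECKS = 187
WITH_CHECKS = 186


def _read(name: str) -> pd.DataFrame:
    with files("plancheck").joinpath(f"data/{name}").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_issue_counts() -> pd.DataFrame:
    """Issue counts per category and period (columns: ``category``,
    ``section``, ``pre_count``, ``with_count``)."""
    df = _read("audit_issue_counts.csv")
    unknown = set(df["category"]) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"bundled dataset has unknown categories: {unknown}")
    return df


def load_timing_summary() -> pd.DataFrame:
    """Per-person timing summaries (mean/median minutes per check and check
    counts for both periods), indexed by checker letter, last row
    ``Overall``."""
    return _read("audit_timing_summary.csv").set_index("checker")


def issue_records_from_counts(counts: pd.DataFrame | None = None) -> list[IssueRecord]:
    """Expand a per-category count table into individual issue records, the
    input form the audit operations consume."""
    if counts is None:
        counts = load_issue_counts()
    records: list[IssueRecord] = []
    for _, row in counts.iterrows():
        records.extend(
            IssueRecord(period=Period.PRE, category=row["category"])
            for _ in range(int(row["pre_count"]))
        )
        records.extend(
            IssueRecord(period=Period.WITH, category=row["category"])
            for _ in range(int(row["with_count"]))
        )
    return records
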