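"""Cohort-level accounting of reportable variants by sequencing tier.

Aggregates case-disposition records into the standard two-by-two summary —
{STR expansion, other variant types} x {no long-read required, long-read
required} — with row/column totals, percentages of all reportable cases, and
the reportable fraction of the full cohort. A case with both an STR and
another reportable variant counts in the STR row.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CaseRecord",
    "CohortSummary",
    "summarize_cohort",
    "per_locus_table",
    "round1",
]


def round1(x: float) -> float:
    """Round half away from zero to 1 decimal (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    has_reportable: bool
    variant_types: frozenset[str]  # subset of {"STR", "other"}
    required_long_read: bool

    def __post_init__(self) -> None:
        if bool(self.variant_types) != self.has_reportable:
            raise ValueError("variant_types empty iff not has_reportable")
        if not self.variant_types <= {"STR", "other"}:
            raise ValueError(f"unknown variant types {self.variant_types}")


@dataclass
class CohortSummary:
    """Counts and percentages of reportable cases by variant type and tier."""

    cells: dict[tuple[str, str], int]  # (row in {STR, other}) x (tier)
    n_total_cohort: int
    n_negative: int

    ROWS = ("STR", "other")
    TIERS = ("no_long_read", "long_read")

    @property
    def total_reportable(self) -> int:
        return sum(self.cells.values())

    def row_total(self, row: str) -> int:
        return sum(self.cells[(row, t)] for t in self.TIERS)

    def col_total(self, tier: str) -> int:
        return sum(self.cells[(r, tier)] for r in self.ROWS)

    def pct(self, count: int) -> Optional[float]:
        """Percentage of all reportable cases, to 1 decimal."""
        if self.total_reportable == 0:
            return None
        return round1(100.0 * count / self.total_reportable)

    @property
    def pct_reportable_of_cohort(self) -> Optional[float]:
        if self.n_total_cohort == 0:
            return None
        return round1(100.0 * self.total_reportable / self.n_total_cohort)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ROWS:
            rows.append(
                {
                    "row": r,
                    "no_long_read": self.cells[(r, "no_long_read")],
                    "long_read": self.cells[(r, "long_read")],
                    "total": self.row_total(r),
                    "pct_no_long_read": self.pct(self.cells[(r, "no_long_read")]),
                    "pct_long_read": self.pct(self.cells[(r, "long_read")]),
                    "pct_total": self.pct(self.row_total(r)),
                }
            )
        rows.append(
            {
                "row": "total",
                "no_long_read": self.col_total("no_long_read"),
                "long_read": self.col_total("long_read"),
                "total": self.total_reportable,
                "pct_no_long_read": self.pct(self.col_total("no_long_read")),
                "pct_long_read": self.pct(self.col_total("long_read")),
                "pct_total": self.pct(self.total_reportable),
            }
        )
        return pd.DataFrame(rows)


def summarize_cohort(
    records: Sequence[CaseRecord], n_total_cohort: Optional[int] = None
) -> CohortSummary:
    """Tabulate case records into a :class:`CohortSummary`.

    ``n_total_cohort`` defaults to ``len(records)``; it may exceed it when
    negative cases are represented only by the cohort size.
    """
    if n_total_cohort is None:
        n_total_cohort = len(records)
    if n_total_cohort < len(records):
        raise ValueError("n_total_cohort smaller than the record count")
    cells = {
        (r, t): 0 for r in CohortSummary.ROWS for t in CohortSummary.TIERS
    }
    n_negative = n_total_cohort - 0  # adjusted below
    n_reportable = 0
    for rec in records:
        if not rec.has_reportable:
            continue
        n_reportable += 1
        row = "STR" if "STR" in rec.variant_types else "other"
        tier = "long_read" if rec.required_long_read else "no_long_read"
        cells[(row, tier)] += 1
    n_negative = n_total_cohort - n_reportable
    return CohortSummary(
        cells=cells, n_total_cohort=n_total_cohort, n_negative=n_negative
    )


def per_locus_table(cases: Iterable[tuple[str, bool]]) -> pd.DataFrame:
    """Per-locus counts by tier.

    ``cases`` yields (locus_id, required_long_read) pairs; returns a frame
    with columns locus_id, no_long_read, long_read, total, sorted by
    locus_id. Order of input does not matter.
    """
    counts: dict[str, list[int]] = {}
    for locus_id, lr in cases:
        c = counts.setdefault(locus_id, [0, 0])
        c[1 if lr else 0] += 1
    rows = [
        {
            "locus_id": lid,
            "no_long_read": c[0],
            "long_read": c[1],
            "total": c[0] + c[1],
        }
        for lid, c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["locus_id", "no_long_read", "long_read", "total"]
    )
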