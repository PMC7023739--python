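"""Attendance analysis for the clinic's scheduled appointments.

Appointment attendance at a post-term pregnancy clinic is unusually low
because women give birth before their slot.  This module reproduces the
clinic's before/after-guideline attendance comparison from printed counts:
attendance proportions, a Pearson chi-square test on the 2x2
attended/not-attended by period table (no continuity correction), and the
ratio-style percentage growth in attended appointments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AttendanceCounts",
    "attendance_proportion",
    "two_proportion_chi_square",
    "percent_ratio_change",
    "load_attendance_counts",
]


@dataclass(frozen=True)
class AttendanceCounts:
    """Attended vs scheduled appointment counts for one period."""

    period_label: str
    attended: int
    scheduled: int

    def __post_init__(self) -> None:
        if self.scheduled <= 0:
            raise ValueError(f"{self.period_label}: scheduled must be > 0")
        if not 0 <= self.attended <= self.scheduled:
            raise ValueError(f"{self.period_label}: need 0 <= attended <= scheduled")

    @property
    def missed(self) -> int:
        return self.scheduled - self.attended


def attendance_proportion(c: AttendanceCounts) -> float:
    """Probability of attendance: attended / scheduled."""
    return c.attended / c.scheduled


def two_proportion_chi_square(
    c1: AttendanceCounts, c2: AttendanceCounts
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 attendance table, without correction.

    Returns (statistic, df, p).  Identical to the squared pooled-variance
    two-sample z statistic on the proportions; df is always 1.
    """
    table = np.array([[c1.attended, c1.missed], [c2.attended, c2.missed]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def percent_ratio_change(earlier: int, later: int) -> float:
    """Growth expressed as a ratio percentage: 100 * later / earlier.

    Under this convention "increased by 436%" means the later count is 4.36
    times the earlier one (e.g. 200 -> 872 attended appointments).
    """
    if earlier <= 0:
        raise ValueError("baseline count must be > 0")
    return 100.0 * later / earlier


def load_attendance_counts(path: Optional[str] = None) -> list[AttendanceCounts]:
    """Read period,attended,scheduled rows (packaged clinic counts by default)."""
    if path is None:
        ref = importlib_resources.files("posttermclinic.data") / "attendance.csv"
        fh = ref.open("r", newline="")
    else:
        fh = open(path, newline="")
    with fh:
        return [
            AttendanceCounts(row["period"], int(row["attended"]), int(row["scheduled"]))
            for row in csv.DictReader(fh)
        ]
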