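"""Grouping, result tables and configuration comparisons.

The 32 resource/pathway combinations are labelled by a group id 0-7 (the
resource triple: midwives, doctors, CTG machines) and a subgroup letter a-d
(arrival pattern x consultation order), e.g. the currently staffed clinic
with everyone arriving at opening and seeing the midwife first is ``0a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .experiments import (
    KPI_NAMES,
    RESOURCE_COMBOS,
    SUBGROUP_COMBOS,
    TrialSummary,
)
from .optimisation import CapacityResult

__all__ = [
    "GroupLabel",
    "assign_group_labels",
    "combo_for_label",
    "build_kpi_table",
    "compare_configurations",
    "format_clock_time",
    "kpi_table_to_markdown",
]

_GROUP_BY_RESOURCES = {triple: gid for gid, triple in enumerate(RESOURCE_COMBOS)}
_SUBGROUP_BY_PATTERN = {pair: "abcd"[sid] for sid, pair in enumerate(SUBGROUP_COMBOS)}


@dataclass(frozen=True)
class GroupLabel:
    """Group (0-7, resource triple) and subgroup (a-d, pattern/order) label."""

    group_id: int
    subgroup_id: str

    def __str__(self) -> str:
        return f"{self.group_id}{self.subgroup_id}"


def assign_group_labels(combo: tuple) -> GroupLabel:
    """Label an (X1, X2, X3, X4, X5) combination, e.g. (All, Mid, 2, 2, 3) -> 0a."""
    x1, x2, x3, x4, x5 = combo
    try:
        gid = _GROUP_BY_RESOURCES[(x3, x4, x5)]
    except KeyError:
        raise ValueError(f"resources {(x3, x4, x5)} outside the 2/3 x 2/3 x 3/4 lattice")
    try:
        sid = _SUBGROUP_BY_PATTERN[(x1, x2)]
    except KeyError:
        raise ValueError(f"pattern/order pair {(x1, x2)} not in the study design")
    return GroupLabel(gid, sid)


def combo_for_label(label: Union[GroupLabel, str]) -> tuple:
    """Inverse of :func:`assign_group_labels`."""
    if isinstance(label, str):
        label = GroupLabel(int(label[:-1]), label[-1])
    x3, x4, x5 = RESOURCE_COMBOS[label.group_id]
    x1, x2 = SUBGROUP_COMBOS["abcd".index(label.subgroup_id)]
    return (x1, x2, x3, x4, x5)


def format_clock_time(minutes_since_midnight: float) -> str:
    """Render minutes since midnight as zero-padded HH:MM:SS."""
    if not 0 <= minutes_since_midnight < 1440:
        raise ValueError(f"clock minutes out of range: {minutes_since_midnight}")
    total_seconds = round(minutes_since_midnight * 60.0)
    h, rem = divmod(total_seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def build_kpi_table(results: Sequence[CapacityResult]) -> pd.DataFrame:
    """The 32-row capacity/KPI table, ordered 0a..7d (base case first).

    Columns carry the inputs X1..X5, the capacity X0/Y1, the last-checkout
    time rendered HH:MM:SS with its half-width in seconds, and the time KPIs
    Y3-Y7 as means (2 decimals) with 95% half-widths.
    """
    if len(results) != 32:
        raise ValueError(f"expected 32 capacity results, got {len(results)}")
    rows = []
    for res in results:
        label = assign_group_labels(res.combo)
        x1, x2, x3, x4, x5 = res.combo
        row = {
            "configuration": str(label),
            "x1": x1, "x2": x2, "x3": x3, "x4": x4, "x5": x5,
            "x0_y1": res.max_feasible_x0,
        }
        if res.kpis_at_max is None:
            rows.append(row)
            continue
        means = res.kpis_at_max.kpi_means
        hws = res.kpis_at_max.kpi_ci_halfwidths
        row["y2_clock"] = format_clock_time(means["y2_last_checkout"])
        row["y2_hw_seconds"] = round(hws["y2_last_checkout"] * 60.0)
        for name in KPI_NAMES[2:]:
            short = name.split("_")[0]
            row[f"{short}_mean"] = round(means[name], 2)
            row[f"{short}_hw"] = round(hws[name], 2)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values("configuration", kind="stable").reset_index(drop=True)
    _check_table_consistency(frame)
    return frame


def _check_table_consistency(frame: pd.DataFrame) -> None:
    """Internal consistency: half-width cells non-negative, labels unique."""
    hw_cols = [c for c in frame.columns if c.endswith("_hw") or c.endswith("_hw_seconds")]
    for col in hw_cols:
        if (frame[col].dropna() < 0).any():
            raise AssertionError(f"negative confidence half-width in {col}")
    if frame["configuration"].duplicated().any():
        raise AssertionError("duplicate configuration labels")


def compare_configurations(a: TrialSummary, b: TrialSummary) -> dict[str, dict]:
    """Per-KPI change from configuration ``a`` to ``b``.

    Sign convention: a *reduction* from a to b is positive.  Percentages are
    100 * (a - b) / a, so "LoS reduced by 16.4%" and "doctor wait increased
    by 153.5%" (a negative reduction) both read off directly; a zero baseline
    KPI leaves the percentage undefined (``None``).
    """
    report: dict[str, dict] = {}
    for name in KPI_NAMES:
        base = a.kpi_means[name]
        other = b.kpi_means[name]
        reduction = base - other
        pct = None if base == 0 else 100.0 * reduction / base
        report[name] = {
            "baseline": base,
            "comparator": other,
            "reduction": reduction,
            "reduction_pct": None if pct is None else round(pct, 1),
        }
    return report


def kpi_table_to_markdown(frame: pd.DataFrame, path: Optional[Union[str, Path]] = None) -> str:
    """A plain Markdown rendering of the capacity/KPI table."""
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join(["---"] * len(cols)) + "|"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
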