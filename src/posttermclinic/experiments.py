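"""Full-factorial configuration sweeps and multi-replication trials.

A *trial* is a set of independent replications of one clinic configuration,
summarised per KPI by the mean and a 95% normal-approximation confidence
half-width (1.96 * sd / sqrt(n)).  The factorial space is the 2x2x2x2x2
lattice of arrival pattern, consultation order, midwives, doctors and CTG
machines crossed with the 19 demand levels X0 = 2..20 (608 configurations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .clinic_model import (
    ClinicConfiguration,
    compute_day_kpis,
    replication_streams,
    run_clinic_day,
)
from .service_distributions import FittedDistribution, fit_all

__all__ = [
    "KPI_NAMES",
    "RESOURCE_COMBOS",
    "SUBGROUP_COMBOS",
    "TrialSummary",
    "enumerate_combos",
    "enumerate_factorial_configurations",
    "run_trial",
    "export_trial_results",
    "import_trial_results",
]

logger = logging.getLogger(__name__)

KPI_NAMES = (
    "y1_arrivals",
    "y2_last_checkout",
    "y3_mean_los",
    "y4_overrun",
    "y5_midwife_wait",
    "y6_doctor_wait",
    "y7_ctg_connection_wait",
)

#: resource triples (X3, X4, X5) in group order 0..7
RESOURCE_COMBOS = (
    (2, 2, 3), (3, 2, 3), (2, 3, 3), (3, 3, 3),
    (2, 2, 4), (3, 2, 4), (2, 3, 4), (3, 3, 4),
)
#: (X1, X2) pairs in subgroup order a..d
SUBGROUP_COMBOS = (("All", "Mid"), ("Half", "Mid"), ("All", "Doc"), ("Half", "Doc"))

_FACTOR_COLUMNS = ("x0", "x1", "x2", "x3", "x4", "x5")


@dataclass
class TrialSummary:
    """KPI means and 95% half-widths over the replications of one trial."""

    configuration: ClinicConfiguration
    n_reps: int
    kpi_means: dict[str, float]
    kpi_ci_halfwidths: dict[str, float]
    n_invalid_runs: int = 0
    master_seed: Optional[int] = None

    @property
    def feasible_within_hours(self) -> bool:
        """Whether the trial-mean last checkout is at or before closing."""
        return self.kpi_means["y2_last_checkout"] <= self.configuration.close_time + 1e-9


def enumerate_combos(
    levels: Optional[Mapping[str, Sequence]] = None,
) -> list[tuple]:
    """All (X1, X2, X3, X4, X5) combinations, in group/subgroup order."""
    if levels is None:
        return [(x1, x2, x3, x4, x5)
                for (x3, x4, x5) in RESOURCE_COMBOS
                for (x1, x2) in SUBGROUP_COMBOS]
    combos = []
    for x3 in levels.get("x3", (2, 3)):
        for x4 in levels.get("x4", (2, 3)):
            for x5 in levels.get("x5", (3, 4)):
                for x1 in levels.get("x1", ("All", "Half")):
                    for x2 in levels.get("x2", ("Mid", "Doc")):
                        combos.append((x1, x2, x3, x4, x5))
    return combos


def enumerate_factorial_configurations(
    x0_range: tuple[int, int] = (2, 20),
    levels: Optional[Mapping[str, Sequence]] = None,
    **config_overrides,
) -> list[ClinicConfiguration]:
    """The full-factorial configuration space, deterministically ordered.

    Combinations follow the group (resource triple) then subgroup (arrival
    pattern x consultation order) ordering; within a combination the demand
    level X0 ascends.  The default lattice yields 608 configurations.
    """
    lo, hi = x0_range
    if hi < lo:
        raise ValueError(f"empty x0 range [{lo}, {hi}]")
    combos = enumerate_combos(levels)
    return [
        ClinicConfiguration(
            arrivals_x0=x0,
            arrival_pattern_x1=x1,
            consult_order_x2=x2,
            midwives_x3=x3,
            doctors_x4=x4,
            ctg_machines_x5=x5,
            **config_overrides,
        )
        for (x1, x2, x3, x4, x5) in combos
        for x0 in range(lo, hi + 1)
    ]


def run_trial(
    config: ClinicConfiguration,
    n_reps: int = 10_000,
    master_seed: int = 0,
    dists: Optional[Mapping[str, FittedDistribution]] = None,
) -> TrialSummary:
    """Run ``n_reps`` independent replications of one configuration.

    Replication ``i`` draws from substreams derived from
    ``(master_seed, i, activity)`` only, so results are independent of
    execution order and common random numbers hold across configurations.
    Invalid replications (a woman still in the clinic at the horizon) are
    excluded from the summary and counted.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if dists is None:
        dists = fit_all()
    rows = np.empty((n_reps, len(KPI_NAMES)))
    n_invalid = 0
    n_valid = 0
    for rep in range(n_reps):
        streams = replication_streams(master_seed, rep)
        day = run_clinic_day(config, dists, streams)
        if not day.valid:
            n_invalid += 1
            logger.warning(
                "invalid run: replication %d of %s exceeded the horizon", rep, config
            )
            continue
        kpis = compute_day_kpis(day)
        rows[n_valid] = [getattr(kpis, name) for name in KPI_NAMES]
        n_valid += 1
    if n_valid == 0:
        raise RuntimeError(f"all {n_reps} replications invalid for {config}")
    data = rows[:n_valid]
    means = data.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # sd of 1 valid rep
        sds = data.std(axis=0, ddof=1)
    halfwidths = 1.96 * sds / np.sqrt(n_valid)
    return TrialSummary(
        configuration=config,
        n_reps=n_reps,
        kpi_means=dict(zip(KPI_NAMES, means.tolist())),
        kpi_ci_halfwidths=dict(zip(KPI_NAMES, halfwidths.tolist())),
        n_invalid_runs=n_invalid,
        master_seed=master_seed,
    )


def _summary_row(s: TrialSummary) -> dict:
    c = s.configuration
    row = {
        "x0": c.arrivals_x0,
        "x1": c.arrival_pattern_x1,
        "x2": c.consult_order_x2,
        "x3": c.midwives_x3,
        "x4": c.doctors_x4,
        "x5": c.ctg_machines_x5,
        "n_reps": s.n_reps,
        "n_invalid_runs": s.n_invalid_runs,
        "master_seed": s.master_seed,
    }
    for name in KPI_NAMES:
        row[f"{name}_mean"] = s.kpi_means[name]
        row[f"{name}_hw"] = s.kpi_ci_halfwidths[name]
    return row


def export_trial_results(
    summaries: Sequence[TrialSummary], path: Union[str, Path] = None
) -> pd.DataFrame:
    """One CSV row per configuration: inputs, KPI means and half-widths.

    Returns the frame; writes it to ``path`` when given.  Full float
    precision is kept so a re-import round-trips losslessly.
    """
    if not summaries:
        raise ValueError("no trial summaries to export")
    frame = pd.DataFrame([_summary_row(s) for s in summaries])
    if path is not None:
        frame.to_csv(path, index=False, float_format="%.17g")
    return frame


def import_trial_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a frame written by :func:`export_trial_results`."""
    return pd.read_csv(path)
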