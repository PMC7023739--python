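"""Treatment-capacity search: the most women a configuration can serve.

For a fixed resource/pathway combination (X1..X5) the demand level X0 is
*feasible* when the trial-mean time the last woman checks out is at or
before closing (10:30).  Treatment capacity is the largest feasible X0 in
2..20.  Every demand level is evaluated (no early stopping), so sampling
noise in the feasibility boundary cannot truncate the search; subject to the
capacity being maximal, a lower mean overrun (Y4) is preferred when ranking
alternative combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .clinic_model import ClinicConfiguration
from .experiments import TrialSummary, enumerate_combos, run_trial
from .service_distributions import FittedDistribution, fit_all

__all__ = ["CapacityResult", "find_max_treatment_capacity", "optimise_all_combos"]

X0_MIN, X0_MAX = 2, 20


@dataclass
class CapacityResult:
    """Capacity search outcome for one (X1, X2, X3, X4, X5) combination."""

    combo: tuple
    max_feasible_x0: Optional[int]
    feasibility_map: dict[int, bool] = field(default_factory=dict)
    kpis_at_max: Optional[TrialSummary] = None
    trials: dict[int, TrialSummary] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.max_feasible_x0 is not None


def find_max_treatment_capacity(
    combo: tuple,
    dists: Optional[Mapping[str, FittedDistribution]] = None,
    n_reps: int = 10_000,
    master_seed: int = 0,
    x0_range: tuple[int, int] = (X0_MIN, X0_MAX),
    **config_overrides,
) -> CapacityResult:
    """Scan every demand level and return the largest feasible one.

    ``combo`` is (X1, X2, X3, X4, X5).  A level is feasible when the
    trial-mean last checkout is <= closing time.  With no feasible level the
    result is flagged (``max_feasible_x0 = None``) rather than raising.
    """
    if n_reps < 100:
        raise ValueError("capacity search needs n_reps >= 100")
    if dists is None:
        dists = fit_all()
    x1, x2, x3, x4, x5 = combo
    result = CapacityResult(combo=combo, max_feasible_x0=None)
    for x0 in range(x0_range[0], x0_range[1] + 1):
        config = ClinicConfiguration(
            arrivals_x0=x0,
            arrival_pattern_x1=x1,
            consult_order_x2=x2,
            midwives_x3=x3,
            doctors_x4=x4,
            ctg_machines_x5=x5,
            **config_overrides,
        )
        trial = run_trial(config, n_reps=n_reps, master_seed=master_seed, dists=dists)
        result.trials[x0] = trial
        result.feasibility_map[x0] = trial.feasible_within_hours
    feasible_levels = [x0 for x0, ok in result.feasibility_map.items() if ok]
    if feasible_levels:
        result.max_feasible_x0 = max(feasible_levels)
        result.kpis_at_max = result.trials[result.max_feasible_x0]
    return result


def optimise_all_combos(
    dists: Optional[Mapping[str, FittedDistribution]] = None,
    n_reps: int = 10_000,
    master_seed: int = 0,
    **kwargs,
) -> list[CapacityResult]:
    """Capacity search over all 32 combinations, in group/subgroup order."""
    if dists is None:
        dists = fit_all()
    return [
        find_max_treatment_capacity(
            combo, dists=dists, n_reps=n_reps, master_seed=master_seed, **kwargs
        )
        for combo in enumerate_combos()
    ]
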