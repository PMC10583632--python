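"""Scenario experiments: unconstrained demand, mergers, bed reduction.

Three orchestrations of the engine:

* **unconstrained demand** — run a unit with and without its capacity
  constraint; the difference in absolute mean occupancy is the "loss"
  attributable to turned-away patients, an estimate of unmet demand
  that historical data cannot provide directly;
* **merger** — pool two or more units' beds (arrivals and discharges
  still per origin unit) and compare the merged occupancy with the sum
  of the individual constrained baselines;
* **bed reduction** — find how many pooled beds can be removed while
  the merged occupancy still meets the combined baseline service level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .simulate import (
    SimulationConfig,
    SimulationSummary,
    UnitSpec,
    child_seeds,
    merge_units,
    run_replications,
)

__all__ = [
    "ScenarioResult",
    "UnconstrainedResult",
    "experiment_unconstrained",
    "experiment_merge",
    "find_removable_beds",
]


@dataclass
class UnconstrainedResult:
    """Potential vs realised occupancy for one unit."""

    unit_id: str
    potential_occupancy: float
    potential_ci95: tuple[float, float]
    constrained_occupancy: float
    constrained_ci95: tuple[float, float]
    loss: float
    loss_ci95: tuple[float, float]
    turned_away_per_year: float


@dataclass
class ScenarioResult:
    """One merger scenario row (baseline sum, merged occupancy, gain)."""

    scenario_id: str
    units: list[str]
    pooled_beds: int
    baseline_sum: float
    merged_occupancy: float
    occupancy_increase: float
    increase_ci95: tuple[float, float]
    removable_beds: int | None
    turned_away_per_year: float


def experiment_unconstrained(
    unit: UnitSpec,
    admission_coeffs: Mapping,
    discharge_coeffs: Mapping,
    config: SimulationConfig,
) -> UnconstrainedResult:
    """Loss of occupancy due to the capacity constraint for one unit.

    The constrained and unconstrained runs use independent substreams
    derived from the configured seed; the loss CI combines the two
    run-level standard errors.
    """
    s_unc, s_con = child_seeds(config.seed, 2)
    potential = run_replications(
        [unit], admission_coeffs, discharge_coeffs,
        replace(config, seed=s_unc, capacity_mode="unconstrained"),
    )
    constrained = run_replications(
        [unit], admission_coeffs, discharge_coeffs,
        replace(config, seed=s_con, capacity_mode="constrained"),
    )
    loss = potential.absolute_mean_occupancy - constrained.absolute_mean_occupancy
    se = float(np.hypot(potential.standard_error, constrained.standard_error))
    return UnconstrainedResult(
        unit_id=unit.unit_id,
        potential_occupancy=potential.absolute_mean_occupancy,
        potential_ci95=potential.ci95,
        constrained_occupancy=constrained.absolute_mean_occupancy,
        constrained_ci95=constrained.ci95,
        loss=loss,
        loss_ci95=(loss - 1.96 * se, loss + 1.96 * se),
        turned_away_per_year=constrained.mean_turned_away_per_year,
    )


def _baselines(
    unit_list: Sequence[UnitSpec],
    admission_coeffs: Mapping,
    discharge_coeffs: Mapping,
    config: SimulationConfig,
    seeds: Sequence[int],
) -> list[SimulationSummary]:
    return [
        run_replications(
            [u], admission_coeffs, discharge_coeffs,
            replace(config, seed=s, capacity_mode="constrained"),
        )
        for u, s in zip(unit_list, seeds)
    ]


def experiment_merge(
    unit_list: Sequence[UnitSpec],
    admission_coeffs: Mapping,
    discharge_coeffs: Mapping,
    config: SimulationConfig,
    scenario_id: str | None = None,
) -> ScenarioResult:
    """Occupancy gain from pooling beds, with a run-level difference CI.

    The increase CI pairs merged and baseline runs by replication index
    (all summaries share ``n_runs``), so it reflects the spread of the
    per-run differences.
    """
    seeds = child_seeds(config.seed, len(unit_list) + 1)
    baselines = _baselines(unit_list, admission_coeffs, discharge_coeffs, config, seeds[:-1])
    merged = merge_units(
        unit_list, admission_coeffs, discharge_coeffs,
        replace(config, seed=seeds[-1], capacity_mode="constrained"),
    )
    baseline_runs = np.sum([b.per_run_values for b in baselines], axis=0)
    diffs = merged.per_run_values - baseline_runs
    inc = float(diffs.mean())
    half = 1.96 * float(diffs.std(ddof=1)) / np.sqrt(len(diffs)) if len(diffs) > 1 else 0.0
    return ScenarioResult(
        scenario_id=scenario_id or "+".join(u.unit_id for u in unit_list),
        units=[u.unit_id for u in unit_list],
        pooled_beds=sum(u.bed_capacity for u in unit_list),
        baseline_sum=float(baseline_runs.mean()),
        merged_occupancy=merged.absolute_mean_occupancy,
        occupancy_increase=inc,
        increase_ci95=(inc - half, inc + half),
        removable_beds=None,
        turned_away_per_year=merged.mean_turned_away_per_year,
    )


def _merged_summary(
    unit_list: Sequence[UnitSpec],
    admission_coeffs: Mapping,
    discharge_coeffs: Mapping,
    config: SimulationConfig,
    beds_removed: int,
) -> SimulationSummary:
    pooled = sum(u.bed_capacity for u in unit_list) - beds_removed
    return run_replications(
        unit_list, admission_coeffs, discharge_coeffs, config, pooled_capacity=pooled
    )


def find_removable_beds(
    unit_list: Sequence[UnitSpec],
    admission_coeffs: Mapping,
    discharge_coeffs: Mapping,
    config: SimulationConfig,
    target: float | None = None,
    scenario_id: str | None = None,
) -> ScenarioResult:
    """Largest number of pooled beds removable at a preserved service level.

    Service level is the combined absolute mean occupancy (default
    target: the sum of the individual constrained baselines).  Beds are
    removed one at a time under common random numbers (the same master
    seed for every capacity level) and the sweep stops at the first
    capacity whose merged occupancy falls more than one Monte-Carlo
    standard error below the target — occupancy is non-decreasing in
    capacity, so the first failure is terminal.
    """
    ids = [u.unit_id for u in unit_list]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate unit ids: {ids}")
    seeds = child_seeds(config.seed, len(unit_list) + 1)
    if target is None:
        baselines = _baselines(unit_list, admission_coeffs, discharge_coeffs, config, seeds[:-1])
        target = float(sum(b.absolute_mean_occupancy for b in baselines))
    if target <= 0:
        raise ValueError("target occupancy must be positive")
    pooled = sum(u.bed_capacity for u in unit_list)
    merged_config = replace(config, seed=seeds[-1], capacity_mode="constrained")

    removable = 0
    kept_summary: SimulationSummary | None = None
    for k in range(0, pooled):
        summary = _merged_summary(
            unit_list, admission_coeffs, discharge_coeffs, merged_config, beds_removed=k
        )
        eps = summary.standard_error
        if summary.absolute_mean_occupancy >= target - eps:
            removable = k
            kept_summary = summary
        else:
            break
    if kept_summary is None:
        warnings.warn(
            f"target occupancy {target:.3f} unattainable even at full pooled "
            f"capacity {pooled}; no beds can be removed"
        )
        kept_summary = _merged_summary(
            unit_list, admission_coeffs, discharge_coeffs, merged_config, beds_removed=0
        )
        removable = 0
    inc = kept_summary.absolute_mean_occupancy - target
    half = 1.96 * kept_summary.standard_error
    return ScenarioResult(
        scenario_id=scenario_id or "+".join(ids),
        units=list(ids),
        pooled_beds=pooled,
        baseline_sum=float(target),
        merged_occupancy=kept_summary.absolute_mean_occupancy,
        occupancy_increase=inc,
        increase_ci95=(inc - half, inc + half),
        removable_beds=removable,
        turned_away_per_year=kept_summary.mean_turned_away_per_year,
    )
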