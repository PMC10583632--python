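"""Discrete-time occupancy engine.

Time advances in 24-hour steps; all stochastic events for a day are
drawn at the midnight that begins it, in a fixed order:

1. every inpatient is discharged with the weekday-dependent probability
   of their *origin* unit (uniform(0,1) draw against the probability);
2. each unit draws its potential admissions from a Poisson distribution
   with the regression mean for the day; the draws are pooled into one
   tagged list;
3. available beds = (pooled capacity − occupancy before discharges) +
   F, where F ~ Binomial(D, freed_bed_availability) applies the 50–50
   rule — a bed vacated during the day is usable for a same-day
   admission only about half the time;
4. if more potential patients than available beds, a uniformly random
   subset is admitted and the rest are turned away (in unconstrained
   mode everyone is admitted);
5. admitted patients join the inpatient list with their origin tag.

The midnight census is recorded *after* the update, i.e. it is the
occupancy entering the next day, which makes summed census equal total
patient-nights.  Replications start from an empty unit, discard a
warm-up window from the census average, and append a cool-down window
so every stay admitted in the core year can complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .calibration import (
    AdmissionCoefficients,
    DischargeCoefficients,
    admission_mean,
    discharge_probability,
)

__all__ = [
    "UnitSpec",
    "Inpatient",
    "SimulationConfig",
    "SimulationSummary",
    "Stay",
    "StepResult",
    "RunResult",
    "step_day",
    "simulate_run",
    "run_replications",
    "merge_units",
]


@dataclass(frozen=True)
class UnitSpec:
    unit_id: str
    bed_capacity: int

    def __post_init__(self) -> None:
        if int(self.bed_capacity) != self.bed_capacity or self.bed_capacity < 1:
            raise ValueError("bed_capacity must be a positive integer")


@dataclass(frozen=True)
class Inpatient:
    """A patient on the list, tagged with the unit whose discharge model applies."""

    origin_unit_id: str
    admission_day: int


@dataclass(frozen=True)
class SimulationConfig:
    n_runs: int = 100
    core_days: int = 365
    warmup_days: int = 14
    cooldown_days: int = 7
    start_date: date = date(2017, 1, 1)
    seed: int = 0
    capacity_mode: str = "constrained"
    freed_bed_availability: float = 0.5

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if min(self.core_days, self.warmup_days, self.cooldown_days) < 0 or self.core_days < 1:
            raise ValueError("day counts must be non-negative (core_days >= 1)")
        if self.capacity_mode not in {"constrained", "unconstrained"}:
            raise ValueError("capacity_mode must be 'constrained' or 'unconstrained'")
        if not 0.0 <= self.freed_bed_availability <= 1.0:
            raise ValueError("freed_bed_availability must be in [0, 1]")


@dataclass
class SimulationSummary:
    """Replication-level summary of absolute mean occupancy."""

    absolute_mean_occupancy: float
    sd_over_runs: float
    ci95: tuple[float, float]
    mean_turned_away_per_year: float
    per_run_values: np.ndarray
    per_run_turned_away: np.ndarray

    @property
    def standard_error(self) -> float:
        return self.sd_over_runs / np.sqrt(len(self.per_run_values))


class Stay(NamedTuple):
    origin_unit_id: str
    admission_day: int  # day index relative to the first core day
    discharge_day: int


class StepResult(NamedTuple):
    inpatients: list[Inpatient]
    admitted: int
    turned_away: int
    discharged: list[Inpatient]


def step_day(
    inpatients: Sequence[Inpatient],
    day: date,
    units: Sequence[UnitSpec],
    admission_coeffs: Mapping[str, AdmissionCoefficients],
    discharge_coeffs: Mapping[str, DischargeCoefficients],
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    day_index: int = 0,
    pooled_capacity: int | None = None,
    admissions_open: bool = True,
) -> StepResult:
    """One midnight update; see the module docstring for the five steps.

    ``admissions_open=False`` skips step 2 (used when draining the unit
    past the simulation horizon so every stay can complete).
    """
    if pooled_capacity is None:
        pooled_capacity = sum(u.bed_capacity for u in units)
    occupancy_before = len(inpatients)
    if config.capacity_mode == "constrained" and occupancy_before > pooled_capacity:
        raise ValueError("inpatient list exceeds pooled capacity")

    # (1) discharges: one uniform draw per inpatient, in list order
    p_by_unit = {u.unit_id: discharge_probability(discharge_coeffs[u.unit_id], day) for u in units}
    kept: list[Inpatient] = []
    discharged: list[Inpatient] = []
    draws = rng.random(occupancy_before)
    for patient, u01 in zip(inpatients, draws):
        (discharged if u01 < p_by_unit[patient.origin_unit_id] else kept).append(patient)

    # (2) potential admissions, pooled with origin tags, in unit order
    potentials: list[str] = []
    if admissions_open:
        for u in units:
            mu = admission_mean(admission_coeffs[u.unit_id], day)
            potentials.extend([u.unit_id] * int(rng.poisson(mu)))

    # (3)+(4) capacity check with the 50-50 freed-bed rule
    freed_usable = int(rng.binomial(len(discharged), config.freed_bed_availability))
    if config.capacity_mode == "unconstrained":
        admitted_tags = potentials
        turned_away = 0
    else:
        # F <= D guarantees the next census never exceeds pooled capacity
        available = (pooled_capacity - occupancy_before) + freed_usable
        if len(potentials) > available:
            order = rng.permutation(len(potentials))
            admitted_tags = [potentials[i] for i in order[:available]]
            turned_away = len(potentials) - available
        else:
            admitted_tags = potentials
            turned_away = 0

    # (5) admitted patients join the list
    new_list = kept + [Inpatient(tag, day_index) for tag in admitted_tags]
    return StepResult(new_list, len(admitted_tags), turned_away, discharged)


@dataclass
class RunResult:
    census: np.ndarray  # midnight census, core days only
    turned_away: int  # total over core days
    stays: list[Stay] = field(default_factory=list)


def simulate_run(
    units: Sequence[UnitSpec],
    admission_coeffs: Mapping[str, AdmissionCoefficients],
    discharge_coeffs: Mapping[str, DischargeCoefficients],
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    pooled_capacity: int | None = None,
    collect_stays: bool = False,
    extend_until_empty: bool = False,
) -> RunResult:
    """A single trajectory over warm-up + core + cool-down days.

    Simulation day ``warmup_days`` corresponds to ``config.start_date``,
    so the core window covers the configured calendar year and the
    warm-up precedes it.  Stay bookkeeping (``collect_stays``) records
    every admission with day indices relative to the first core day;
    ``extend_until_empty`` keeps stepping past the horizon until every
    inpatient has been discharged, so no stay is left open.
    """
    total = config.warmup_days + config.core_days + config.cooldown_days
    day0 = config.start_date - timedelta(days=config.warmup_days)
    census = np.zeros(config.core_days, dtype=int)
    core_lo = config.warmup_days
    core_hi = config.warmup_days + config.core_days
    turned_away_core = 0
    stays: list[Stay] = []
    inpatients: list[Inpatient] = []

    t = 0
    while t < total or (extend_until_empty and inpatients):
        day = day0 + timedelta(days=t)
        result = step_day(
            inpatients,
            day,
            units,
            admission_coeffs,
            discharge_coeffs,
            config,
            rng,
            day_index=t - core_lo,
            pooled_capacity=pooled_capacity,
            admissions_open=t < total,
        )
        if collect_stays:
            for patient in result.discharged:
                stays.append(Stay(patient.origin_unit_id, patient.admission_day, t - core_lo))
        inpatients = result.inpatients
        if core_lo <= t < core_hi:
            census[t - core_lo] = len(inpatients)
            turned_away_core += result.turned_away
        t += 1
        if t > total + 10_000:
            raise RuntimeError("extend_until_empty did not terminate; discharge probability ~ 0")
    return RunResult(census=census, turned_away=turned_away_core, stays=stays)


def _summarise(run_means: np.ndarray, run_turned: np.ndarray, core_days: int) -> SimulationSummary:
    n = len(run_means)
    mean = float(run_means.mean())
    sd = float(run_means.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n)
    return SimulationSummary(
        absolute_mean_occupancy=mean,
        sd_over_runs=sd,
        ci95=(mean - half, mean + half),
        mean_turned_away_per_year=float(run_turned.mean()) * 365.0 / core_days,
        per_run_values=run_means,
        per_run_turned_away=run_turned.astype(float),
    )


def run_replications(
    units: Sequence[UnitSpec],
    admission_coeffs: Mapping[str, AdmissionCoefficients],
    discharge_coeffs: Mapping[str, DischargeCoefficients],
    config: SimulationConfig,
    *,
    pooled_capacity: int | None = None,
) -> SimulationSummary:
    """Independent replications with per-run substreams from the master seed.

    Each run value is the mean midnight census over the core days; the
    95% CI is the normal approximation over the ``n_runs`` run values.
    """
    missing = [u.unit_id for u in units if u.unit_id not in admission_coeffs or u.unit_id not in discharge_coeffs]
    if missing:
        raise ValueError(f"missing coefficient sets for units: {missing}")
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    run_means = np.empty(config.n_runs)
    run_turned = np.empty(config.n_runs, dtype=int)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        result = simulate_run(
            units, admission_coeffs, discharge_coeffs, config, rng, pooled_capacity=pooled_capacity
        )
        run_means[i] = result.census.mean()
        run_turned[i] = result.turned_away
    return _summarise(run_means, run_turned, config.core_days)


def merge_units(
    unit_list: Sequence[UnitSpec],
    admission_coeffs: Mapping[str, AdmissionCoefficients],
    discharge_coeffs: Mapping[str, DischargeCoefficients],
    config: SimulationConfig,
    beds_removed: int = 0,
) -> SimulationSummary:
    """Simulate two or more units as one pooled-capacity unit.

    Arrivals are generated per origin unit and discharges use the
    origin unit's coefficients; only the bed pool is shared (optionally
    reduced by ``beds_removed``).  Turn-away under the pooled constraint
    is uniformly random across the pooled potential list.
    """
    ids = [u.unit_id for u in unit_list]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate unit ids in merge: {ids}")
    if len(unit_list) < 2:
        raise ValueError("merging requires at least two distinct units")
    pooled = sum(u.bed_capacity for u in unit_list) - beds_removed
    if beds_removed < 0 or pooled < 1:
        raise ValueError("beds_removed must be in [0, pooled capacity - 1]")
    return run_replications(
        unit_list, admission_coeffs, discharge_coeffs, config, pooled_capacity=pooled
    )


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]
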