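"""Synthetic admission-record generator with known ground truth.

Real unit-level admission data is rarely shareable, so this module
generates record files with exactly the statistical structure the model
assumes: daily Poisson arrivals whose mean follows a weekday + month
linear predictor, and per-inpatient next-day discharge draws from a
weekday logistic model.  Because the truth is known, calibration and
the full pipeline can be tested end to end.

Presets are scaled to the study-population ranges of small community
admission-avoidance units: bed capacities between 6 and 72, mean length
of stay around 3 days (5 for the small preset), and absolute mean
occupancies well below capacity for all but the busiest unit.  Length
of stay under the model is geometric-like (one discharge draw per
night), which matches the empirical mean but not the empirical spread —
occupancy, not the stay distribution, is the quantity of interest.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logit

from .calibration import AdmissionCoefficients, DischargeCoefficients, discharge_probability
from .records import AdmissionRecord, OccupancySeries, write_records
from .simulate import SimulationConfig, UnitSpec, simulate_run

__all__ = ["Scenario", "PRESETS", "make_scenario", "generate_records"]


@dataclass
class Scenario:
    """A fully specified ground-truth world for the generator."""

    units: list[UnitSpec]
    true_admission_coeffs: dict[str, AdmissionCoefficients]
    true_discharge_coeffs: dict[str, DischargeCoefficients]
    years: int = 1
    seed: int = 0
    capacity_mode: str = "constrained"
    start_date: date = date(2017, 1, 1)

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.capacity_mode not in {"constrained", "unconstrained"}:
            raise ValueError("capacity_mode must be 'constrained' or 'unconstrained'")
        for u in self.units:
            if u.unit_id not in self.true_admission_coeffs:
                raise ValueError(f"missing admission coefficients for {u.unit_id!r}")
            if u.unit_id not in self.true_discharge_coeffs:
                raise ValueError(f"missing discharge coefficients for {u.unit_id!r}")
        # implied mean LOS (1/p averaged over weekdays) must be finite
        probe = date(2017, 1, 2)  # a Monday
        for uid, dis in self.true_discharge_coeffs.items():
            for k in range(7):
                p = discharge_probability(dis, date.fromordinal(probe.toordinal() + k))
                if not p > 0.0:
                    raise ValueError(f"discharge probability ~0 for {uid!r}; mean LOS not finite")

    def mean_los_nights(self, unit_id: str) -> float:
        """Rough implied mean stay: 1 / (weekday-average discharge probability)."""
        probe = date(2017, 1, 2)
        ps = [
            discharge_probability(self.true_discharge_coeffs[unit_id], date.fromordinal(probe.toordinal() + k))
            for k in range(7)
        ]
        return 1.0 / float(np.mean(ps))


def _adm(intercept, weekday=None, month=None):
    return AdmissionCoefficients(intercept, dict(weekday or {}), dict(month or {}))


def _dis(p_monday, weekday=None):
    return DischargeCoefficients(float(logit(p_monday)), dict(weekday or {}))


def _preset_units() -> dict[str, tuple[UnitSpec, AdmissionCoefficients, DischargeCoefficients]]:
    # One entry per archetype: (unit, admission truth, discharge truth).
    # Scales: ~0.5 arrivals/day at 6 beds with ~5-night stays (small),
    # ~3/day at 14 beds, ~15/day at 72 beds, ~2.2/day at 15 beds, all
    # ~3-night stays; weekend dips in both arrivals and discharges,
    # a summer-holiday dip in arrivals.
    small = (
        UnitSpec("small", 6),
        _adm(0.60, {"saturday": -0.20, "sunday": -0.25}, {"july": -0.15, "august": -0.10}),
        _dis(0.20, {"saturday": -0.35, "sunday": -0.45}),
    )
    medium = (
        UnitSpec("medium", 14),
        _adm(
            3.2,
            {"tuesday": 0.2, "saturday": -0.8, "sunday": -1.0},
            {"february": 0.2, "july": -0.5, "august": -0.3, "december": 0.3},
        ),
        _dis(0.30, {"saturday": -0.30, "sunday": -0.40}),
    )
    large = (
        UnitSpec("large", 72),
        _adm(16.0, {"saturday": -3.0, "sunday": -4.0}, {"july": -2.0, "august": -1.0}),
        _dis(1 / 3, {"saturday": -0.20, "sunday": -0.30}),
    )
    mid_low = (
        UnitSpec("mid_low", 15),
        _adm(2.4, {"saturday": -0.6, "sunday": -0.7}, {"july": -0.4}),
        _dis(1 / 3, {"saturday": -0.25, "sunday": -0.35}),
    )
    return {"small": small, "medium": medium, "large": large, "mid_low": mid_low}


def _build_presets() -> dict[str, Scenario]:
    u = _preset_units()
    presets = {}
    for name in ("small", "medium", "large"):
        unit, adm, dis = u[name]
        presets[name] = Scenario(
            units=[unit],
            true_admission_coeffs={unit.unit_id: adm},
            true_discharge_coeffs={unit.unit_id: dis},
        )
    four = [u["medium"], u["small"], u["large"], u["mid_low"]]
    presets["four_unit"] = Scenario(
        units=[t[0] for t in four],
        true_admission_coeffs={t[0].unit_id: t[1] for t in four},
        true_discharge_coeffs={t[0].unit_id: t[2] for t in four},
    )
    return presets


PRESETS = _build_presets()


def make_scenario(
    preset: str | None = None,
    *,
    units: Sequence[UnitSpec] | None = None,
    admission_coeffs: Mapping[str, AdmissionCoefficients] | None = None,
    discharge_coeffs: Mapping[str, DischargeCoefficients] | None = None,
    years: int = 1,
    seed: int = 0,
    capacity_mode: str | None = None,
    start_date: date = date(2017, 1, 1),
) -> Scenario:
    """Build a scenario from a named preset or explicit parameters.

    Exactly one of ``preset`` or the (units, admission_coeffs,
    discharge_coeffs) triple must be supplied.
    """
    explicit = [units, admission_coeffs, discharge_coeffs]
    if preset is not None:
        if any(x is not None for x in explicit):
            raise ValueError("give either a preset or explicit parameters, not both")
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        base = copy.deepcopy(PRESETS[preset])
        return Scenario(
            units=base.units,
            true_admission_coeffs=base.true_admission_coeffs,
            true_discharge_coeffs=base.true_discharge_coeffs,
            years=years,
            seed=seed,
            capacity_mode=capacity_mode or base.capacity_mode,
            start_date=start_date,
        )
    if any(x is None for x in explicit):
        raise ValueError("explicit scenarios need units, admission_coeffs and discharge_coeffs")
    return Scenario(
        units=list(units),
        true_admission_coeffs=dict(admission_coeffs),
        true_discharge_coeffs=dict(discharge_coeffs),
        years=years,
        seed=seed,
        capacity_mode=capacity_mode or "constrained",
        start_date=start_date,
    )


def generate_records(
    scenario: Scenario, path: str | Path | None = None
) -> tuple[list[AdmissionRecord], OccupancySeries]:
    """Simulate the scenario once and emit every stay as a record.

    The window is ``years * 365`` days from the scenario start date with
    no warm-up (an empty unit on day one, like a newly opened unit); the
    simulation is extended past the window until every inpatient is
    discharged, so no record has a missing discharge date.  The returned
    census series is the simulator's own trace and equals
    ``compute_daily_occupancy`` of the emitted records on the window.

    Optional demographics are filled from fixed marginals typical of the
    setting (median age ~80, about two-thirds female); they are never
    predictors anywhere.
    """
    n_days = scenario.years * 365
    config = SimulationConfig(
        n_runs=1,
        core_days=n_days,
        warmup_days=0,
        cooldown_days=0,
        start_date=scenario.start_date,
        seed=scenario.seed,
        capacity_mode=scenario.capacity_mode,
    )
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    result = simulate_run(
        scenario.units,
        scenario.true_admission_coeffs,
        scenario.true_discharge_coeffs,
        config,
        rng,
        collect_stays=True,
        extend_until_empty=True,
    )
    demo_rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    records = []
    n_long = 0
    for stay in sorted(result.stays, key=lambda s: (s.admission_day, s.origin_unit_id)):
        adm = scenario.start_date.fromordinal(scenario.start_date.toordinal() + stay.admission_day)
        dis = scenario.start_date.fromordinal(scenario.start_date.toordinal() + stay.discharge_day)
        if (dis - adm).days > 21:
            n_long += 1
        age = float(np.clip(np.round(demo_rng.normal(79.0, 12.0)), 18, 105))
        sex = "F" if demo_rng.random() < 0.66 else "M"
        records.append(
            AdmissionRecord(
                unit_id=stay.origin_unit_id,
                admission_date=adm,
                discharge_date=dis,
                age=age,
                sex=sex,
                home_municipality=stay.origin_unit_id,
            )
        )
    if n_long:
        import warnings

        warnings.warn(f"{n_long} generated stays exceed 21 days and would be dropped by cleaning")
    occ = OccupancySeries(start_date=scenario.start_date, counts=result.census)
    if path is not None:
        write_records(records, path)
    return records, occ


def scenario_truth_dict(scenario: Scenario) -> dict:
    """JSON-serialisable ground truth (for a --truth file)."""
    from .calibration import _adm_to_dict, _dis_to_dict

    return {
        "units": [{"unit_id": u.unit_id, "bed_capacity": u.bed_capacity} for u in scenario.units],
        "admission": {k: _adm_to_dict(v) for k, v in scenario.true_admission_coeffs.items()},
        "discharge": {k: _dis_to_dict(v) for k, v in scenario.true_discharge_coeffs.items()},
        "years": scenario.years,
        "seed": scenario.seed,
        "capacity_mode": scenario.capacity_mode,
        "start_date": scenario.start_date.isoformat(),
    }
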