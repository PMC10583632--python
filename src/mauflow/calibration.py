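"""Calibration of the two stochastic sub-models from admission records.

Two regressions drive the simulator:

* an **admission model** — ordinary least squares of the daily number of
  admissions on weekday and month dummies (reference Monday / January),
  fitted only on *low-occupancy* days (census at or below the unit's
  median) so the fitted mean reflects unconstrained, "potential" demand
  rather than demand censored by a full unit;
* a **discharge model** — logistic regression of the next-day discharge
  indicator for each inpatient-midnight on the weekday of the coming
  day, fitted on all days (occupancy does not censor discharges).

The fitted coefficients feed :func:`admission_mean` (a Poisson mean,
clamped at zero) and :func:`discharge_probability` (an inverse-logit
probability) during simulation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .records import AdmissionRecord, OccupancySeries

__all__ = [
    "WEEKDAYS",
    "MONTHS",
    "AdmissionCoefficients",
    "DischargeCoefficients",
    "CoefficientSet",
    "select_low_occupancy_days",
    "fit_admission_model",
    "fit_discharge_model",
    "admission_mean",
    "discharge_probability",
    "save_coefficients",
    "load_coefficients",
]

WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")
MONTHS = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)
_REF_WEEKDAY = "monday"
_REF_MONTH = "january"


def _check_effects(effects: Mapping[str, float], allowed: Sequence[str], ref: str, what: str) -> None:
    for key, value in effects.items():
        if key == ref:
            raise ValueError(f"reference level {ref!r} must not carry an explicit {what} effect")
        if key not in allowed:
            raise ValueError(f"unknown {what} level {key!r}")
        if not math.isfinite(value):
            raise ValueError(f"{what} effect for {key!r} is not finite")


@dataclass
class AdmissionCoefficients:
    """Linear-model coefficients for expected daily potential admissions.

    ``intercept`` is the Monday/January mean; ``weekday_effects`` and
    ``month_effects`` are additive offsets (admissions/day) for the
    non-reference levels.  Missing levels are implicitly zero.
    """

    intercept: float
    weekday_effects: dict[str, float] = field(default_factory=dict)
    month_effects: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None
    weekday_se: dict[str, float] = field(default_factory=dict)
    month_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        _check_effects(self.weekday_effects, WEEKDAYS, _REF_WEEKDAY, "weekday")
        _check_effects(self.month_effects, MONTHS, _REF_MONTH, "month")


@dataclass
class DischargeCoefficients:
    """Logistic-model coefficients (log-odds) for next-day discharge.

    ``intercept`` is the Monday log-odds; ``weekday_effects`` shift the
    log-odds on other weekdays (reference Monday, implicitly zero).
    """

    intercept: float
    weekday_effects: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None
    weekday_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        _check_effects(self.weekday_effects, WEEKDAYS, _REF_WEEKDAY, "weekday")


@dataclass
class CoefficientSet:
    """Both calibrated sub-models for one unit, as stored on disk."""

    unit_id: str
    admission: AdmissionCoefficients
    discharge: DischargeCoefficients
    bed_capacity: int | None = None


def select_low_occupancy_days(occ: OccupancySeries) -> list[date]:
    """Days whose midnight census is at or below the series median.

    The median is taken over the full supplied series, so at least half
    of the days are always retained (ties count as retained).
    """
    if len(occ) == 0:
        raise ValueError("occupancy series is empty")
    median = float(np.median(occ.counts))
    return [d for d, c in zip(occ.dates, occ.counts) if c <= median]


def _daily_admission_counts(
    records: Iterable[AdmissionRecord], retained_days: Sequence[date]
) -> pd.DataFrame:
    days = sorted(set(retained_days))
    counts = {d: 0 for d in days}
    for rec in records:
        if rec.admission_date in counts:
            counts[rec.admission_date] += 1
    return pd.DataFrame(
        {
            "count": [counts[d] for d in days],
            "weekday": [WEEKDAYS[d.weekday()] for d in days],
            "month": [MONTHS[d.month - 1] for d in days],
        },
        index=pd.Index(days, name="date"),
    )


def _dummy_design(df: pd.DataFrame, column: str, levels: Sequence[str], ref: str, what: str) -> pd.DataFrame:
    present = [lv for lv in levels if (df[column] == lv).any()]
    absent = [lv for lv in levels if lv not in present]
    if ref not in present:
        warnings.warn(
            f"reference {what} {ref!r} absent from the data; its effect is "
            "absorbed into the intercept of the remaining levels",
            stacklevel=3,
        )
    if absent:
        warnings.warn(f"{what} levels with no observations dropped: {absent}", stacklevel=3)
    cols = {}
    for lv in present:
        if lv == ref:
            continue
        cols[f"{what}[{lv}]"] = (df[column] == lv).astype(float)
    return pd.DataFrame(cols, index=df.index)


def fit_admission_model(
    records: Sequence[AdmissionRecord], retained_days: Sequence[date]
) -> AdmissionCoefficients:
    """OLS of daily admission counts on weekday and month dummies.

    Retained days with zero admissions enter as zeros; admissions on
    non-retained days are ignored.  Month effects are only estimable
    when the retained days span more than one month.
    """
    df = _daily_admission_counts(records, retained_days)
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    X = pd.concat([X, _dummy_design(df, "weekday", WEEKDAYS, _REF_WEEKDAY, "weekday")], axis=1)
    if df["month"].nunique() > 1:
        X = pd.concat([X, _dummy_design(df, "month", MONTHS, _REF_MONTH, "month")], axis=1)
    else:
        warnings.warn("retained days span a single month; month effects not estimable")
    n_params = X.shape[1]
    if len(df) < n_params + 1:
        raise ValueError(
            f"too few retained days to fit the admission model: "
            f"{len(df)} days for {n_params} parameters "
            f"(need at least {n_params + 1})"
        )
    fit = sm.OLS(df["count"].astype(float), X).fit()
    weekday_effects, month_effects = {}, {}
    weekday_se, month_se = {}, {}
    for name, value in fit.params.items():
        se = float(fit.bse[name])
        if name.startswith("weekday["):
            weekday_effects[name[8:-1]] = float(value)
            weekday_se[name[8:-1]] = se
        elif name.startswith("month["):
            month_effects[name[6:-1]] = float(value)
            month_se[name[6:-1]] = se
    return AdmissionCoefficients(
        intercept=float(fit.params["intercept"]),
        weekday_effects=weekday_effects,
        month_effects=month_effects,
        intercept_se=float(fit.bse["intercept"]),
        weekday_se=weekday_se,
        month_se=month_se,
    )


def inpatient_day_table(records: Sequence[AdmissionRecord]) -> pd.DataFrame:
    """Expand stays into one row per inpatient-midnight at risk.

    A stay admitted on day *a* and discharged on day *b* contributes
    rows for the coming days ``a+1 .. b``; the outcome is 1 on the last
    of them (the patient leaves within that 24-h period) and 0 before.
    The predictor is the weekday of the coming day.  Same-day stays
    (LOS 0) never face a midnight decision and contribute nothing.
    """
    rows_day, rows_out = [], []
    for rec in records:
        los = rec.length_of_stay
        for k in range(1, los + 1):
            coming = rec.admission_date + timedelta(days=k)
            rows_day.append(WEEKDAYS[coming.weekday()])
            rows_out.append(1.0 if k == los else 0.0)
    return pd.DataFrame({"weekday": rows_day, "discharged": rows_out})


def fit_discharge_model(records: Sequence[AdmissionRecord]) -> DischargeCoefficients:
    """Maximum-likelihood logistic fit of next-day discharge on weekday.

    No occupancy filtering is applied.  Under complete separation (a
    weekday on which every at-risk midnight has the same outcome) a
    warning is issued and the quasi-separated fit is returned with its
    correspondingly large standard errors.
    """
    df = inpatient_day_table(records)
    if df.empty:
        raise ValueError("no inpatient-midnights at risk; cannot fit discharge model")
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    X = pd.concat([X, _dummy_design(df, "weekday", WEEKDAYS, _REF_WEEKDAY, "weekday")], axis=1)
    model = sm.Logit(df["discharged"], X)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = model.fit(disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            fit = model.fit(disp=0, method="bfgs", maxiter=500)
    separation = any("separation" in str(w.message).lower() for w in caught) or (
        np.abs(fit.params.to_numpy()) > 15
    ).any()
    if separation:
        warnings.warn(
            "complete or quasi-complete separation in the discharge model; "
            "coefficients are reported with very large standard errors"
        )
    weekday_effects, weekday_se = {}, {}
    for name, value in fit.params.items():
        if name.startswith("weekday["):
            weekday_effects[name[8:-1]] = float(value)
            weekday_se[name[8:-1]] = float(fit.bse[name])
    return DischargeCoefficients(
        intercept=float(fit.params["intercept"]),
        weekday_effects=weekday_effects,
        intercept_se=float(fit.bse["intercept"]),
        weekday_se=weekday_se,
    )


def admission_mean(coeffs: AdmissionCoefficients, day: date) -> float:
    """Expected potential admissions on ``day`` (clamped at zero).

    The linear predictor is intercept + weekday effect + month effect;
    a negative prediction is not a valid Poisson mean and is clamped to
    zero with a warning.
    """
    mu = (
        coeffs.intercept
        + coeffs.weekday_effects.get(WEEKDAYS[day.weekday()], 0.0)
        + coeffs.month_effects.get(MONTHS[day.month - 1], 0.0)
    )
    if mu < 0.0:
        warnings.warn("negative predicted admission mean clamped to 0")
        return 0.0
    return mu


def discharge_probability(coeffs: DischargeCoefficients, day: date) -> float:
    """Probability that an inpatient leaves during ``day``."""
    eta = coeffs.intercept + coeffs.weekday_effects.get(WEEKDAYS[day.weekday()], 0.0)
    return float(expit(eta))


# ---------------------------------------------------------------------------
# coefficient file I/O (JSON, or YAML by extension)

def _adm_to_dict(c: AdmissionCoefficients) -> dict:
    out = {
        "intercept": c.intercept,
        "weekday_effects": dict(c.weekday_effects),
        "month_effects": dict(c.month_effects),
    }
    if c.intercept_se is not None:
        out["intercept_se"] = c.intercept_se
        out["weekday_se"] = dict(c.weekday_se)
        out["month_se"] = dict(c.month_se)
    return out


def _dis_to_dict(c: DischargeCoefficients) -> dict:
    out = {"intercept": c.intercept, "weekday_effects": dict(c.weekday_effects)}
    if c.intercept_se is not None:
        out["intercept_se"] = c.intercept_se
        out["weekday_se"] = dict(c.weekday_se)
    return out


def save_coefficients(coeff_set: CoefficientSet, path: str | Path) -> None:
    """Write a unit's coefficient pair as JSON (or YAML by extension)."""
    path = Path(path)
    payload = {
        "unit_id": coeff_set.unit_id,
        "bed_capacity": coeff_set.bed_capacity,
        "admission": _adm_to_dict(coeff_set.admission),
        "discharge": _dis_to_dict(coeff_set.discharge),
    }
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_coefficients(path: str | Path) -> CoefficientSet:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    adm = payload["admission"]
    dis = payload["discharge"]
    return CoefficientSet(
        unit_id=payload["unit_id"],
        bed_capacity=payload.get("bed_capacity"),
        admission=AdmissionCoefficients(
            intercept=adm["intercept"],
            weekday_effects=dict(adm.get("weekday_effects", {})),
            month_effects=dict(adm.get("month_effects", {})),
            intercept_se=adm.get("intercept_se"),
            weekday_se=dict(adm.get("weekday_se", {})),
            month_se=dict(adm.get("month_se", {})),
        ),
        discharge=DischargeCoefficients(
            intercept=dis["intercept"],
            weekday_effects=dict(dis.get("weekday_effects", {})),
            intercept_se=dis.get("intercept_se"),
            weekday_se=dict(dis.get("weekday_se", {})),
        ),
    )
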