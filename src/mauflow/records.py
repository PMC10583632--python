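"""Reading, cleaning and summarising admission records.

The raw input is a CSV of de-identified inpatient stays (one row per
admission) with at least ``unit_id``, ``admission_date`` and
``discharge_date`` columns; ``age``, ``sex`` and ``municipality`` are
optional.  Cleaning drops rows with missing or unparseable dates, rows
whose discharge precedes admission, and stays longer than 21 days
(treated as recording errors for short-stay units).

Occupancy is a midnight census: a patient admitted on day *a* and
discharged on day *b* occupies a bed at the midnights ending days
``a .. b-1`` (half-open convention ``[a, b)``), so the total of the
census over days equals total patient-nights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdmissionRecord",
    "OccupancySeries",
    "MAX_LOS_DAYS",
    "read_admission_records",
    "clean_records",
    "compute_daily_occupancy",
    "write_records",
    "write_summary",
]

#: stays longer than this (in whole days) are treated as recording errors
MAX_LOS_DAYS = 21

REQUIRED_COLUMNS = ("unit_id", "admission_date", "discharge_date")
OPTIONAL_COLUMNS = ("age", "sex", "municipality")


@dataclass(frozen=True)
class AdmissionRecord:
    """One cleaned inpatient stay."""

    unit_id: str
    admission_date: date
    discharge_date: date
    age: float | None = None
    sex: str | None = None
    home_municipality: str | None = None

    @property
    def length_of_stay(self) -> int:
        """Length of stay in whole days (nights); 0 for same-day stays."""
        return (self.discharge_date - self.admission_date).days


@dataclass
class OccupancySeries:
    """Daily midnight census starting at ``start_date``."""

    start_date: date
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("census counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(len(self.counts))]

    def mean(self) -> float:
        return float(self.counts.mean())


def clean_records(
    records: Iterable[AdmissionRecord],
) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Apply the stay-level cleaning rules to already-parsed records.

    Returns the retained records and a log of exclusion counts.  Cleaning
    is idempotent: running it on its own output removes nothing.
    """
    log = {"missing_date": 0, "unparseable_date": 0, "negative_los": 0, "los_gt_21": 0}
    kept: list[AdmissionRecord] = []
    for rec in records:
        if rec.admission_date is None or rec.discharge_date is None:
            log["missing_date"] += 1
            continue
        los = rec.length_of_stay
        if los < 0:
            log["negative_los"] += 1
            continue
        if los > MAX_LOS_DAYS:
            log["los_gt_21"] += 1
            continue
        kept.append(rec)
    return kept, log


def _parse_date(value) -> tuple[date | None, str]:
    """Return (date_or_None, status) with status in {ok, missing, bad}."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, "missing"
    text = str(value).strip()
    if not text or text.lower() in {"nan", "na", "none"}:
        return None, "missing"
    ts = pd.to_datetime(text, errors="coerce")
    if pd.isna(ts):
        return None, "bad"
    return ts.date(), "ok"


def read_admission_records(
    path: str | Path, unit_filter: str | None = None
) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Read and clean an admission-records CSV.

    Parameters
    ----------
    path:
        CSV file with a header naming at least the columns
        ``unit_id``, ``admission_date``, ``discharge_date``.
    unit_filter:
        If given, only rows for that unit are considered (the cleaning
        log then refers to that unit only).

    Returns
    -------
    (records, cleaning_log) where ``cleaning_log`` counts excluded rows
    by reason: missing_date, unparseable_date, negative_los, los_gt_21.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records file {path} lacks required columns: {missing_cols}")
    if unit_filter is not None:
        df = df[df["unit_id"] == unit_filter]

    log = {"missing_date": 0, "unparseable_date": 0, "negative_los": 0, "los_gt_21": 0}
    records: list[AdmissionRecord] = []
    for row in df.itertuples(index=False):
        adm, adm_status = _parse_date(row.admission_date)
        dis, dis_status = _parse_date(row.discharge_date)
        if "missing" in (adm_status, dis_status):
            log["missing_date"] += 1
            continue
        if "bad" in (adm_status, dis_status):
            log["unparseable_date"] += 1
            continue
        age = None
        if hasattr(row, "age") and row.age is not None and str(row.age).strip() not in {"", "nan"}:
            try:
                age = float(row.age)
            except ValueError:
                age = None
        sex = getattr(row, "sex", None)
        sex = None if sex is None or str(sex).strip() in {"", "nan"} else str(sex)
        muni = getattr(row, "municipality", None)
        muni = None if muni is None or str(muni).strip() in {"", "nan"} else str(muni)
        records.append(
            AdmissionRecord(
                unit_id=str(row.unit_id),
                admission_date=adm,
                discharge_date=dis,
                age=age,
                sex=sex,
                home_municipality=muni,
            )
        )
    records, stay_log = clean_records(records)
    for key in ("negative_los", "los_gt_21"):
        log[key] += stay_log[key]
    return records, log


def compute_daily_occupancy(
    records: Sequence[AdmissionRecord], start_date: date, n_days: int
) -> OccupancySeries:
    """Midnight census for each of ``n_days`` days from ``start_date``.

    Day *d* counts records with ``admission_date <= d < discharge_date``
    (the patient is present at the midnight ending day *d*).  Records
    that fall entirely outside the window contribute nothing; partial
    overlaps contribute only where they overlap.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    delta = np.zeros(n_days + 1, dtype=int)
    for rec in records:
        s = (rec.admission_date - start_date).days
        e = (rec.discharge_date - start_date).days
        s, e = max(s, 0), min(e, n_days)
        if e > s:
            delta[s] += 1
            delta[e] -= 1
    return OccupancySeries(start_date=start_date, counts=np.cumsum(delta[:-1]))


def write_records(records: Sequence[AdmissionRecord], path: str | Path) -> None:
    """Write records in the canonical CSV schema (ISO-8601 dates)."""
    df = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "admission_date": [r.admission_date.isoformat() for r in records],
            "discharge_date": [r.discharge_date.isoformat() for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "municipality": [r.home_municipality for r in records],
        }
    )
    df.to_csv(path, index=False)


def _flatten_row(row) -> dict:
    if dataclasses.is_dataclass(row) and not isinstance(row, type):
        row = dataclasses.asdict(row)
    elif not isinstance(row, Mapping):
        raise TypeError(f"cannot serialise row of type {type(row)!r}")
    flat: dict = {}
    for key, value in row.items():
        if isinstance(value, (np.ndarray, list)):
            continue  # per-run vectors are not part of the tabular summary
        if isinstance(value, tuple) and len(value) == 2:
            flat[f"{key}_low"], flat[f"{key}_high"] = value
        else:
            flat[key] = value
    return flat


def write_summary(rows, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write one or more result objects as a CSV table.

    Accepts a single dataclass/mapping or a sequence of them; rows are
    written in input order with a stable column order (keys of the first
    row, or ``columns`` for an empty result set, which yields a
    header-only file).  Interval-valued fields (2-tuples) expand to
    ``_low``/``_high`` columns; per-run vectors are dropped.
    """
    if dataclasses.is_dataclass(rows) and not isinstance(rows, type):
        rows = [rows]
    elif isinstance(rows, Mapping):
        rows = [rows]
    flat = [_flatten_row(r) for r in rows]
    if flat:
        columns = list(flat[0].keys())
    df = pd.DataFrame(flat, columns=columns)
    df.to_csv(path, index=False)
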