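"""Weight-record table schema and delimited-text IO.

A weight-record table is a pandas DataFrame with one row per weighing
event.  Columns (the on-disk CSV uses the same names and order):

======================  =======================================================
column                  meaning
======================  =======================================================
``practice_id``         veterinary-practice identifier (int)
``farm_id``             farm identifier, unique across practices (int)
``calf_id``             calf identifier, unique across farms (int)
``birth_date``          calf date of birth (ISO-8601 date)
``recording_date``      date of the weighing (ISO-8601 date)
``age_days``            calf age at weighing, whole days
``weight_kg``           measured weight in kg
``is_estimate``         True when the weight was entered as an estimate
``is_birth_weight``     True for a confirmed birth weight (age 0 record)
======================  =======================================================

Dates are stored as ``datetime64[ns]`` in memory and written as ISO-8601
``YYYY-MM-DD`` strings.  ``age_days`` equals ``recording_date - birth_date``
in whole days whenever both dates are present.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RECORD_COLUMNS = [
    "practice_id",
    "farm_id",
    "calf_id",
    "birth_date",
    "recording_date",
    "age_days",
    "weight_kg",
    "is_estimate",
    "is_birth_weight",
]

_DATE_COLUMNS = ["birth_date", "recording_date"]
_BOOL_COLUMNS = ["is_estimate", "is_birth_weight"]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the record-table schema and core invariants.

    Returns the frame unchanged on success.  Raises ``ValueError`` on a
    missing column, a non-positive weight, or an ``age_days`` that
    disagrees with the date difference.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table is missing columns: {missing}")
    if len(records) == 0:
        return records
    if (records["weight_kg"] <= 0).any():
        n_bad = int((records["weight_kg"] <= 0).sum())
        raise ValueError(f"{n_bad} records have non-positive weight_kg")
    both = records["birth_date"].notna() & records["recording_date"].notna()
    if both.any():
        delta = (
            records.loc[both, "recording_date"] - records.loc[both, "birth_date"]
        ).dt.days
        if (delta != records.loc[both, "age_days"]).any():
            n_bad = int((delta != records.loc[both, "age_days"]).sum())
            raise ValueError(
                f"{n_bad} records have age_days inconsistent with their dates"
            )
    return records


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as CSV with ISO-8601 dates."""
    out = records[RECORD_COLUMNS].copy()
    for col in _DATE_COLUMNS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record table written by :func:`write_records`."""
    records = pd.read_csv(
        path, parse_dates=_DATE_COLUMNS, dtype={c: bool for c in _BOOL_COLUMNS}
    )
    return validate_records(records)
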