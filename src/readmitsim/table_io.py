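"""Reading, writing and validating discharge tables.

A discharge table is a :class:`pandas.DataFrame` with one row per index
discharge.  Required columns are ``patient_id`` (cluster identifier),
``discharge_index`` (1-based chronological ordinal within patient) and the
binary ``outcome`` (30-day readmission indicator).  Optional
``admission_time``/``discharge_time`` timestamp columns support the
merge/label operations.  Covariate columns are, by convention, every column
whose name starts with ``x``.

One CSV dialect is supported (comma separated, UTF-8, header row, ISO-8601
timestamps, outcome column last) so that identical tables serialize to
identical bytes.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

KEY_COLUMNS = ["patient_id", "discharge_index"]
TIME_COLUMNS = ["admission_time", "discharge_time"]
OUTCOME_COLUMN = "outcome"

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


class SchemaError(ValueError):
    """A discharge table violated the schema or its invariants."""


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """Covariate column names (prefix ``x``), in table order."""
    return [c for c in table.columns if c.startswith("x")]


def canonical_column_order(table: pd.DataFrame) -> list[str]:
    cols = list(KEY_COLUMNS)
    cols += [c for c in TIME_COLUMNS if c in table.columns]
    cols += covariate_columns(table)
    cols += [OUTCOME_COLUMN]
    return cols


def validate_discharge_table(
    table: pd.DataFrame, require_timestamps: bool = False
) -> pd.DataFrame:
    """Validate schema and invariants; return the table unchanged.

    Raises :class:`SchemaError` naming the offending column/patient on any
    violation: missing columns, duplicated (patient, index) keys,
    non-binary outcome, non-contiguous discharge_index, non-numeric
    covariates, or index order inconsistent with discharge_time.
    """
    if not isinstance(table, pd.DataFrame):
        raise SchemaError("discharge table must be a pandas DataFrame")
    for col in KEY_COLUMNS + [OUTCOME_COLUMN]:
        if col not in table.columns:
            raise SchemaError(f"missing required column {col!r}")
    if require_timestamps:
        for col in TIME_COLUMNS:
            if col not in table.columns:
                raise SchemaError(f"missing required timestamp column {col!r}")

    if len(table) == 0:
        return table

    outcome = table[OUTCOME_COLUMN]
    if not np.isin(np.asarray(outcome), [0, 1]).all():
        raise SchemaError("column 'outcome' must be binary 0/1")

    dup = table.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        pid = table.loc[dup, "patient_id"].iloc[0]
        raise SchemaError(f"duplicated (patient_id, discharge_index) for patient {pid!r}")

    for col in covariate_columns(table):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"covariate column {col!r} contains non-numeric values")

    # discharge_index must be a contiguous 1..n_i ordinal within each patient
    idx = table.groupby("patient_id", sort=False)["discharge_index"]
    sizes = idx.size()
    mins, maxs, sums = idx.min(), idx.max(), idx.sum()
    expected_sum = sizes * (sizes + 1) // 2
    bad = (mins != 1) | (maxs != sizes) | (sums != expected_sum)
    if bad.any():
        pid = bad[bad].index[0]
        raise SchemaError(
            f"discharge_index not contiguous 1..n_i for patient {pid!r}"
        )

    if all(c in table.columns for c in TIME_COLUMNS):
        sub = table.sort_values(KEY_COLUMNS, kind="stable")
        grp = sub.groupby("patient_id", sort=False)
        if (grp["admission_time"].diff().dropna() < pd.Timedelta(0)).any():
            raise SchemaError("discharge_index order disagrees with admission_time order")
        if (sub["discharge_time"] < sub["admission_time"]).any():
            pid = sub.loc[sub["discharge_time"] < sub["admission_time"], "patient_id"].iloc[0]
            raise SchemaError(f"discharge_time before admission_time for patient {pid!r}")
    return table


def read_discharge_table(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read and validate a discharge-table CSV."""
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed text must error descriptively
        raise SchemaError(f"could not parse CSV: {exc}") from exc
    for col in TIME_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_datetime(table[col], format=TIME_FORMAT)
    validate_discharge_table(table)
    return table[canonical_column_order(table)]


def write_discharge_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated table in the canonical CSV dialect.

    Column order, timestamp format and float formatting are deterministic,
    so equal tables produce byte-identical files.
    """
    validate_discharge_table(table)
    out = table[canonical_column_order(table)].copy()
    for col in TIME_COLUMNS:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime(TIME_FORMAT)
    path = Path(path)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_run_config(params: dict, path: str | Path) -> Path:
    """Write a sidecar YAML file recording generator/study parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return path


def read_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
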