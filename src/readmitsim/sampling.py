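"""Sampling strategies and the patient-level train/validation split.

Two sampling frames are compared throughout the package: the first index
discharge per patient versus all index discharges.  The split is always at
the patient level so that no cluster straddles training and validation —
the integrity property the clustering-aware estimators rely on.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .table_io import validate_discharge_table


def first_discharges(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only each patient's first (chronological) index discharge."""
    validate_discharge_table(table)
    out = table[table["discharge_index"] == 1].reset_index(drop=True)
    return out


def all_discharges(table: pd.DataFrame) -> pd.DataFrame:
    """Identity with schema validation: every index discharge is a row."""
    validate_discharge_table(table)
    return table.reset_index(drop=True)


def split_by_patient(
    table: pd.DataFrame, train_fraction: float = 0.6, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition patients (not rows) into train and validation sets.

    Patients are randomly permuted and the first round(train_fraction * N)
    taken for training (round half up), so every discharge of a patient
    lands on exactly one side.  Deterministic given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    validate_discharge_table(table)
    patients = np.sort(table["patient_id"].unique())
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty

    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    train_ids = set(perm[:n_train])
    mask = table["patient_id"].isin(train_ids)
    train = table[mask].reset_index(drop=True)
    validation = table[~mask].reset_index(drop=True)
    return train, validation
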