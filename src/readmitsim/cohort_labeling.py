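"""Cohort-construction rules for timestamped discharge tables.

Two operations mirror how readmission cohorts are assembled from raw
admission records:

* near-immediate readmissions (gap <= 8 hours by default, typically
  in-hospital transfers) are merged into the index stay, iteratively until
  no short gap remains;
* the binary outcome is then labeled 1 when the patient's next admission
  falls within 30 days (inclusive) of discharge.

Both windows are inclusive at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .table_io import validate_discharge_table

MERGE_WINDOW = pd.Timedelta(hours=8)
READMISSION_WINDOW = pd.Timedelta(days=30)


def _check_ordered_non_overlapping(table: pd.DataFrame) -> None:
    for pid, grp in table.groupby("patient_id", sort=False):
        adm = grp["admission_time"].to_numpy()
        dis = grp["discharge_time"].to_numpy()
        if np.any(np.diff(adm) < np.timedelta64(0, "s")):
            raise ValueError(f"stays of patient {pid!r} are not in admission order")
        if np.any(adm[1:] < dis[:-1]):
            raise ValueError(f"overlapping stays for patient {pid!r}")


def merge_short_interval_readmissions(
    table: pd.DataFrame, window: pd.Timedelta = MERGE_WINDOW
) -> pd.DataFrame:
    """Fuse any stay starting within ``window`` of the previous discharge.

    Fusing extends the earlier stay's discharge_time to the later stay's
    discharge_time and is applied transitively, so a chain of short gaps
    collapses to a single stay.  Covariates are kept from the first stay of
    a fused run; the outcome is kept from the last (it refers to what
    follows the fused stay) and should be refreshed with
    :func:`label_readmissions`.  discharge_index is re-assigned 1..n_i.
    """
    validate_discharge_table(table, require_timestamps=True)
    table = table.sort_values(["patient_id", "discharge_index"], kind="stable")
    _check_ordered_non_overlapping(table)

    pieces = []
    for pid, grp in table.groupby("patient_id", sort=False):
        adm = grp["admission_time"].to_numpy()
        dis = grp["discharge_time"].to_numpy()
        # run id increments whenever the gap to the previous discharge
        # exceeds the window; equal-to-window gaps merge (inclusive)
        gaps = adm[1:] - dis[:-1]
        new_run = np.concatenate([[True], gaps > window])
        run_id = np.cumsum(new_run) - 1

        first = np.flatnonzero(new_run)
        last = np.concatenate([first[1:] - 1, [len(grp) - 1]])
        fused = grp.iloc[first].copy()
        fused["discharge_time"] = dis[last]
        fused["outcome"] = grp["outcome"].to_numpy()[last]
        fused["discharge_index"] = np.arange(1, len(first) + 1)
        pieces.append(fused)
        del run_id  # runs are fully described by first/last

    out = pd.concat(pieces, ignore_index=True)
    return validate_discharge_table(out)


def label_readmissions(
    table: pd.DataFrame, window: pd.Timedelta = READMISSION_WINDOW
) -> pd.DataFrame:
    """Label outcome = 1 iff the next admission is within ``window`` of discharge.

    The window is inclusive at exactly ``window``.  A patient's final
    discharge is labeled 0 (no later admission exists).  Idempotent; row
    count is unchanged.  Merging should be applied first so that short
    transfer gaps do not count as readmissions.
    """
    validate_discharge_table(table, require_timestamps=True)
    table = table.sort_values(["patient_id", "discharge_index"], kind="stable")
    _check_ordered_non_overlapping(table)

    out = table.copy()
    adm = out.groupby("patient_id", sort=False)["admission_time"].shift(-1)
    gap = adm - out["discharge_time"]
    labeled = (gap.notna() & (gap > pd.Timedelta(0)) & (gap <= window)).astype(int)
    out["outcome"] = labeled.to_numpy()
    return validate_discharge_table(out)
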