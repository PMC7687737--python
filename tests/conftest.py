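"""Shared fixtures: small synthetic cohorts and the qualitative study run.

The ``qualitative_study`` fixture is the one expensive computation in the
suite (a multi-seed resampling study on the default informative cohort);
it is session-scoped so every test that inspects it shares one run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from readmitsim import (
    GeneratorConfig,
    StudyConfig,
    generate_cohort,
    run_study,
)

QUALITATIVE_SEEDS = (101, 102, 103, 104, 105)
QUALITATIVE_GRID = (2000, 4000, 6000, 8000)
QUALITATIVE_COHORT_PATIENTS = 9000


def make_singleton_table(x: np.ndarray, y: np.ndarray, name: str = "x1") -> pd.DataFrame:
    """One patient per row — the simplest valid discharge table."""
    return pd.DataFrame(
        {
            "patient_id": np.arange(len(y)),
            "discharge_index": np.ones(len(y), dtype=int),
            name: np.asarray(x, dtype=float),
            "outcome": np.asarray(y, dtype=int),
        }
    )


def make_clustered_table(
    n_clusters: int, seed: int, max_size: int = 4, beta=(0.8, -0.5), frailty_sd: float = 1.0
) -> pd.DataFrame:
    """Small clustered dataset with within-cluster correlated outcomes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_clusters):
        n = int(rng.integers(1, max_size + 1))
        u = rng.normal(0, frailty_sd)
        x = rng.normal(size=(n, len(beta)))
        eta = -0.5 + x @ np.asarray(beta) + u
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        for j in range(n):
            row = {"patient_id": i, "discharge_index": j + 1, "outcome": int(y[j])}
            for k in range(len(beta)):
                row[f"x{k + 1}"] = x[j, k]
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def informative_cohort() -> pd.DataFrame:
    """Default informative cohort (gamma > 0) at a mid-size patient count."""
    return generate_cohort(GeneratorConfig(n_patients=3000), seed=42)


@pytest.fixture(scope="session")
def timeline_cohort() -> pd.DataFrame:
    """Timestamped cohort for merge/label round-trips."""
    return generate_cohort(GeneratorConfig(n_patients=600, timestamps=True), seed=7)


@pytest.fixture(scope="session")
def qualitative_study():
    """Five-seed resampling study on the default cohort, reduced size grid.

    Returns (records, cohorts): tidy records pooled over seeds with a
    ``cohort_seed`` column, and the per-seed cohorts keyed by seed.
    """
    frames, cohorts = [], {}
    for seed in QUALITATIVE_SEEDS:
        cohort = generate_cohort(
            GeneratorConfig(n_patients=QUALITATIVE_COHORT_PATIENTS), seed=seed
        )
        cohorts[seed] = cohort
        result = run_study(cohort, StudyConfig(size_grid=QUALITATIVE_GRID, seed=seed))
        assert not result.failures, f"study cells failed: {result.failures}"
        rec = result.records.copy()
        rec["cohort_seed"] = seed
        frames.append(rec)
    return pd.concat(frames, ignore_index=True), cohorts
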