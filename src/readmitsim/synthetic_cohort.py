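"""Synthetic clustered discharge cohorts with informative cluster size.

The generator emulates the statistical structure of a hospital cohort in
which each patient (cluster) contributes one or more index discharges and
the binary outcome is 30-day all-cause readmission.  A single patient-level
latent propensity ("frailty") u_i ~ N(0, sigma^2) enters BOTH

* the cluster-size intensity:  n_i = 1 + Poisson(lambda * exp(gamma * u_i))
* the outcome logit:           Y_ij ~ Bernoulli(expit(alpha + beta'X_ij + u_i))

so that with gamma > 0 sicker patients both accumulate more discharges and
are readmitted more often — the informative-cluster-size phenomenon that
biases analyses pooling all discharges and motivates cluster-weighted GEE.

Patient-constant covariates are Bernoulli(1/2) recoded to +/-1 (mean 0,
variance 1); discharge-varying covariates are standard normal.

In timeline mode the generator additionally emits admission/discharge
timestamps such that the 30-day labeling rule reconstructs the simulated
outcomes exactly: a readmission corresponds to a next admission 8 hours to
30 days after discharge, a non-readmission to a gap of 30 to 365 days.
Because a patient's final discharge has no subsequent admission, its
outcome is fixed to 0 in timeline mode.

Randomness is split hierarchically per patient from one root seed, so
enlarging ``n_patients`` leaves the draws of existing patients unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .table_io import validate_discharge_table

#: Defaults emulating a cohort where ~10% of first discharges and ~20% of
#: all discharges are followed by a 30-day readmission, about half of the
#: patients have a single discharge, and the mean cluster holds ~2.5-3
#: discharges.  The effect vector mixes strong, weak and null covariates
#: so that variable selection has real work to do at realistic sample
#: sizes.
DEFAULT_COVARIATE_EFFECTS = (0.8, -0.5, 0.3, 0.15, 0.0, 0.6, -0.4, 0.2, -0.1, 0.0)

_STUDY_START = pd.Timestamp("2004-01-01")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic clustered cohort.

    Parameters
    ----------
    n_patients
        Number of patients (clusters).
    frailty_sd
        sigma, standard deviation of the latent patient propensity u_i.
    cluster_rate
        lambda > 0, mean number of excess discharges (beyond the first)
        for a patient with u_i = 0.
    informativeness
        gamma, effect of u_i on the log cluster-size intensity; gamma = 0
        makes cluster size non-informative.
    baseline_logit
        alpha, intercept of the outcome logit.
    covariate_effects
        beta, one log-odds ratio per covariate; constant-covariate effects
        first, then varying-covariate effects.
    n_constant_covariates, n_varying_covariates
        Number of patient-constant and discharge-varying covariates.
    frailty_loading
        How strongly each varying covariate reflects the patient's
        frailty: covariate j is (z + l_j u) / sqrt(1 + l_j^2 sigma^2)
        with l_j = frailty_loading * sign(beta_j), i.e. sicker patients
        drift in the risk-increasing direction of each measured covariate
        (as clinical measurements do).  This is what lets a fitted model's
        predicted risk correlate with cluster size; 0 makes covariates
        pure noise with respect to frailty.
    readmission_window_days, merge_window_hours
        The 30-day outcome window and 8-hour merge window used when
        timestamps are generated.
    timestamps
        Emit admission/discharge timestamps (timeline mode).
    seed
        Default seed when ``generate_cohort`` is called without one.
    """

    n_patients: int = 1000
    frailty_sd: float = 1.1
    cluster_rate: float = 0.65
    informativeness: float = 1.1
    baseline_logit: float = -3.4
    covariate_effects: tuple[float, ...] = DEFAULT_COVARIATE_EFFECTS
    n_constant_covariates: int = 5
    n_varying_covariates: int = 5
    frailty_loading: float = 0.3
    readmission_window_days: float = 30.0
    merge_window_hours: float = 8.0
    timestamps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.covariate_effects = tuple(float(b) for b in self.covariate_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be >= 0")
        if self.cluster_rate <= 0:
            raise ValueError("cluster_rate must be > 0")
        n_cov = self.n_constant_covariates + self.n_varying_covariates
        if len(self.covariate_effects) != n_cov:
            raise ValueError(
                f"covariate_effects has length {len(self.covariate_effects)}, "
                f"expected {n_cov} (n_constant + n_varying)"
            )

    @property
    def covariate_names(self) -> list[str]:
        const = [f"xc{k + 1}" for k in range(self.n_constant_covariates)]
        vary = [f"xv{k + 1}" for k in range(self.n_varying_covariates)]
        return const + vary

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["covariate_effects"] = list(self.covariate_effects)
        return d


def _patient_rng(seed: int, i: int) -> np.random.Generator:
    # spawn_key keeps patient i's stream fixed as n_patients grows
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a validated discharge table.

    Identical ``(config, seed)`` pairs produce identical tables.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    sigma = config.frailty_sd
    lam = config.cluster_rate
    gamma = config.informativeness
    alpha = config.baseline_logit
    beta = np.asarray(config.covariate_effects, dtype=float)
    n_const = config.n_constant_covariates
    n_vary = config.n_varying_covariates
    window = pd.Timedelta(days=config.readmission_window_days)
    merge_h = config.merge_window_hours

    pid_parts, X_parts, y_parts = [], [], []
    idx_parts, adm_parts, dis_parts = [], [], []
    for i in range(config.n_patients):
        rng = _patient_rng(seed, i)
        u = rng.normal(0.0, sigma)
        intensity = lam * np.exp(gamma * u)
        if not np.isfinite(intensity):
            raise FloatingPointError(f"non-finite cluster intensity for patient {i}")
        n_i = 1 + int(rng.poisson(intensity))

        x_const = 2.0 * rng.binomial(1, 0.5, size=n_const) - 1.0
        x_vary = rng.normal(size=(n_i, n_vary))
        if config.frailty_loading != 0 and n_vary:
            load = config.frailty_loading * np.sign(beta[n_const:])
            x_vary = (x_vary + load * u) / np.sqrt(1.0 + load**2 * sigma**2)
        X = (
            np.column_stack([np.tile(x_const, (n_i, 1)), x_vary])
            if n_const + n_vary
            else np.empty((n_i, 0))
        )

        eta = alpha + X @ beta + u
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError(f"non-finite linear predictor for patient {i}")
        y = rng.binomial(1, expit(eta)).astype(int)

        if config.timestamps:
            y[-1] = 0  # no subsequent admission can exist for the last stay
            first_adm = float(rng.uniform(0, 8 * 365))
            los_days = rng.uniform(1.0, 10.0, size=n_i)
            # margins of ~0.1 d at both boundaries keep second-resolution
            # rounding from crossing the merge or outcome windows
            w_days = window / pd.Timedelta(days=1)
            gap_days = np.where(
                y[:-1] == 1,
                rng.uniform(merge_h / 24.0 + 0.1, w_days - 0.1, size=max(n_i - 1, 0)),
                rng.uniform(w_days + 1.0, 365.0, size=max(n_i - 1, 0)),
            )
            adm = first_adm + np.concatenate([[0.0], np.cumsum(los_days[:-1] + gap_days)])
            dis = adm + los_days
            adm_parts.append(adm)
            dis_parts.append(dis)

        pid_parts.append(np.full(n_i, i, dtype=int))
        idx_parts.append(np.arange(1, n_i + 1))
        X_parts.append(X)
        y_parts.append(y)

    rec: dict = {
        "patient_id": np.concatenate(pid_parts),
        "discharge_index": np.concatenate(idx_parts),
    }
    if config.timestamps:
        adm_td = pd.to_timedelta(np.concatenate(adm_parts), unit="D")
        dis_td = pd.to_timedelta(np.concatenate(dis_parts), unit="D")
        rec["admission_time"] = (_STUDY_START + adm_td).floor("s")
        rec["discharge_time"] = (_STUDY_START + dis_td).floor("s")
    X_all = np.concatenate(X_parts, axis=0)
    for k, name in enumerate(config.covariate_names):
        rec[name] = X_all[:, k]
    rec["outcome"] = np.concatenate(y_parts)
    table = pd.DataFrame(rec)
    return validate_discharge_table(table)


@dataclass
class ClusterSummary:
    """Per-cluster descriptives of a discharge table.

    ``log_size_readmission_r`` is NaN (undefined) when all cluster sizes
    are equal, never silently 0.
    """

    n_patients: int
    n_discharges: int
    size_bins: pd.DataFrame  # bin, n_patients, pct_patients, pct_discharges_readmitted
    readmission_counts: pd.Series  # per-patient readmission count, indexed by patient_id
    cluster_sizes: pd.Series
    log_size_readmission_r: float


def cluster_summary(
    table: pd.DataFrame, bin_edges: tuple[int, ...] = (1, 2, 3)
) -> ClusterSummary:
    """Summarize cluster sizes and their coupling with readmission.

    The default bins report patients with exactly 1, exactly 2 and >= 3
    discharges.  The correlation is Pearson r between log cluster size and
    the per-patient readmission count.
    """
    validate_discharge_table(table)
    if len(table) == 0:
        raise ValueError("cluster_summary requires a non-empty table")
    grp = table.groupby("patient_id", sort=True)
    sizes = grp.size()
    counts = grp["outcome"].sum()

    edges = list(bin_edges) + [np.inf]
    labels = [
        str(edges[k]) if edges[k + 1] == edges[k] + 1 else f"{edges[k]}+"
        for k in range(len(bin_edges))
    ]
    rows = []
    for k, label in enumerate(labels):
        mask = (sizes >= edges[k]) & (sizes < edges[k + 1])
        pids = sizes.index[mask]
        sub = table[table["patient_id"].isin(pids)]
        rows.append(
            {
                "bin": label,
                "n_patients": int(mask.sum()),
                "pct_patients": 100.0 * mask.sum() / len(sizes),
                "pct_discharges_readmitted": (
                    100.0 * sub["outcome"].mean() if len(sub) else np.nan
                ),
            }
        )
    bins = pd.DataFrame(rows)

    log_sizes = np.log(sizes.to_numpy(dtype=float))
    if np.ptp(log_sizes) == 0 or counts.std(ddof=0) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(log_sizes, counts.to_numpy(dtype=float))[0, 1])

    return ClusterSummary(
        n_patients=len(sizes),
        n_discharges=len(table),
        size_bins=bins,
        readmission_counts=counts,
        cluster_sizes=sizes,
        log_size_readmission_r=r,
    )
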