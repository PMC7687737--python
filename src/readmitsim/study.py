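"""The resampling experiment over cohort sizes and its analyses.

For each size on a grid (default 2000..17000 patients by 1000), a subset
of patients is drawn from the full cohort, split 60/40 by patient into
training and validation, and each modeling strategy is taken through the
full pipeline — univariate screen, best-subset selection, final fit —
then scored on validation with the five performance measures.  The four
strategies are:

* ``LR-first`` — logistic regression on the first discharge per patient;
* ``LR-all``  — logistic regression on all discharges;
* ``GEE``     — exchangeable GEE on all discharges;
* ``CWGEE``   — cluster-weighted GEE on all discharges.

Each model is validated in its own sampling frame: LR-first on validation
first discharges, the rest on all validation discharges.

``slope_analysis`` regresses each metric on cohort size (OLS, slope per
1000 patients) and adds an analysis-of-covariance comparison of slopes
across methods per metric.  ``discharge_correlations`` quantifies the
informative-cluster-size coupling: the correlation between a patient's
number of discharges and their number of readmissions, and between the
number of discharges and model-predicted risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import FitResult, predict_probability
from .performance import PerformanceReport, evaluate
from .sampling import first_discharges, split_by_patient
from .table_io import covariate_columns, validate_discharge_table
from .variable_selection import best_subset_select, univariate_screen

logger = logging.getLogger(__name__)

METHODS = ("LR-first", "LR-all", "GEE", "CWGEE")
METRICS = PerformanceReport.METRICS  # auc, correlation, coef_discrimination, brier, scaled_brier

_ESTIMATOR_OF = {"LR-first": "LR", "LR-all": "LR", "GEE": "GEE", "CWGEE": "CWGEE"}


@dataclass
class StudyConfig:
    """Grid and settings of the resampling study."""

    size_grid: tuple[int, ...] = tuple(range(2000, 17001, 1000))
    replicates: int = 1
    train_fraction: float = 0.6
    methods: tuple[str, ...] = METHODS
    screen_alpha: float = 0.1
    select_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["size_grid"] = list(self.size_grid)
        d["methods"] = list(self.methods)
        return d


@dataclass
class StudyResult:
    """Tidy long-format records plus any per-cell failure notes."""

    records: pd.DataFrame  # size, replicate, method, seed, metric, value
    failures: list[dict] = field(default_factory=list)
    config: StudyConfig | None = None

    def pivot(self, metric: str) -> pd.DataFrame:
        """size x method table of one metric (mean over replicates)."""
        sub = self.records[self.records["metric"] == metric]
        return sub.pivot_table(index="size", columns="method", values="value")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "study_records.csv", index=False)
        if self.failures:
            pd.DataFrame(self.failures).to_csv(out / "study_failures.csv", index=False)


def _cell_seed(seed: int, size: int, replicate: int) -> int:
    # derived seeds stay below 2**31 and are decoupled across cells
    ss = np.random.SeedSequence(seed, spawn_key=(size, replicate))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def fit_method(
    train: pd.DataFrame,
    method: str,
    candidates: list[str] | None = None,
    screen_alpha: float = 0.1,
    select_alpha: float = 0.05,
):
    """Run screen + best-subset + final fit for one modeling strategy.

    Returns (fit, screen_result, selection_result).  ``train`` must
    already be in the method's sampling frame.
    """
    if candidates is None:
        candidates = covariate_columns(train)
    estimator = _ESTIMATOR_OF[method]
    screen = univariate_screen(train, candidates, estimator, alpha=screen_alpha)
    if not screen.selected:
        raise RuntimeError("no covariate passed the univariate screen")
    selection = best_subset_select(train, screen.selected, estimator, alpha=select_alpha)
    return selection.fit, screen, selection


def _frame(table: pd.DataFrame, method: str) -> pd.DataFrame:
    return first_discharges(table) if method == "LR-first" else table


def run_study(cohort: pd.DataFrame, config: StudyConfig) -> StudyResult:
    """Execute the full (size x method) resampling grid.

    Fully deterministic given ``config.seed``.  A cell whose pipeline
    fails records NaN for all metrics together with the reason, and the
    study continues.
    """
    validate_discharge_table(cohort)
    patients = np.sort(cohort["patient_id"].unique())
    if len(patients) < max(config.size_grid):
        raise ValueError(
            f"cohort has {len(patients)} patients < max grid size {max(config.size_grid)}"
        )
    candidates = covariate_columns(cohort)
    rows, failures = [], []
    for size in config.size_grid:
        for rep in range(config.replicates):
            cell_seed = _cell_seed(config.seed, size, rep)
            rng = np.random.default_rng(cell_seed)
            chosen = rng.choice(patients, size=size, replace=False)
            subset = cohort[cohort["patient_id"].isin(chosen)]
            train, valid = split_by_patient(subset, config.train_fraction, seed=cell_seed)
            for method in config.methods:
                tr, va = _frame(train, method), _frame(valid, method)
                try:  # noqa: SIM105 — a failed cell must not stop the grid
                    fit, _, _ = fit_method(
                        tr, method, candidates, config.screen_alpha, config.select_alpha
                    )
                    rep_out = evaluate(fit, va)
                    values = {m: getattr(rep_out, m) for m in METRICS}
                    values["observed_rate"] = rep_out.observed_rate
                except Exception as exc:  # record and continue
                    logger.warning("cell (%s, %s, %s) failed: %s", size, method, rep, exc)
                    failures.append(
                        {"size": size, "method": method, "replicate": rep, "reason": str(exc)}
                    )
                    values = {m: float("nan") for m in METRICS}
                    values["observed_rate"] = float("nan")
                for metric, value in values.items():
                    rows.append(
                        {
                            "size": size,
                            "replicate": rep,
                            "method": method,
                            "seed": cell_seed,
                            "metric": metric,
                            "value": value,
                        }
                    )
    records = pd.DataFrame(rows)
    return StudyResult(records=records, failures=failures, config=config)


def slope_analysis(result: StudyResult) -> pd.DataFrame:
    """OLS slope of each metric against cohort size, per method.

    Slopes are reported per 1000 patients.  Two ANCOVA-style comparisons
    are attached per metric: ``p_interaction`` tests slope equality across
    methods (method x size interaction on top of method-specific
    intercepts) and ``p_common_slope`` tests a zero common slope in the
    parallel-lines model.  NaN cells are excluded pairwise; the count
    used is reported per row.
    """
    import statsmodels.formula.api as smf

    rec = result.records[result.records["metric"].isin(METRICS)].copy()
    rec = rec.dropna(subset=["value"])
    rec["size_k"] = rec["size"] / 1000.0
    sizes_per = rec.groupby(["method", "metric"])["size"].nunique()
    if (sizes_per < 3).any():
        raise ValueError("slope analysis needs >= 3 grid sizes per (method, metric)")

    rows = []
    for metric, sub in rec.groupby("metric"):
        full = smf.ols("value ~ C(method) * size_k", data=sub).fit()
        parallel = smf.ols("value ~ C(method) + size_k", data=sub).fit()
        from statsmodels.stats.anova import anova_lm

        try:
            p_inter = float(anova_lm(parallel, full).iloc[1]["Pr(>F)"])
        except (ValueError, np.linalg.LinAlgError):
            p_inter = float("nan")
        p_common = float(parallel.pvalues.get("size_k", float("nan")))
        for method, msub in sub.groupby("method"):
            ols = smf.ols("value ~ size_k", data=msub).fit()
            rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "slope_per_1000": float(ols.params["size_k"]),
                    "se": float(ols.bse["size_k"]),
                    "p_slope": float(ols.pvalues["size_k"]),
                    "n_cells": int(len(msub)),
                    "p_interaction": p_inter,
                    "p_common_slope": p_common,
                }
            )
    return pd.DataFrame(rows).sort_values(["metric", "method"]).reset_index(drop=True)


@dataclass
class DischargeCorrelations:
    """Coupling of cluster size with observed and predicted readmission."""

    r_count: float  # discharges vs readmission count
    r_log_count: float  # log discharges vs readmission count
    r_predicted: dict  # method -> Pearson r (discharges vs mean predicted risk)
    r_log_risk: float  # log discharges vs per-patient readmission proportion
    bin_table: pd.DataFrame  # per discharge-count bin: patients, % readmitted


def discharge_correlations(
    cohort: pd.DataFrame, fits: dict[str, FitResult] | None = None
) -> DischargeCorrelations:
    """Correlate per-patient discharge counts with readmission and risk."""
    validate_discharge_table(cohort)
    grp = cohort.groupby("patient_id", sort=True)
    n_i = grp.size().to_numpy(dtype=float)
    count = grp["outcome"].sum().to_numpy(dtype=float)
    prop = grp["outcome"].mean().to_numpy(dtype=float)

    def _r(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_pred = {}
    if fits:
        for method, fit in fits.items():
            p = predict_probability(fit, cohort)
            mean_p = (
                pd.Series(p, index=cohort["patient_id"].to_numpy())
                .groupby(level=0)
                .mean()
                .sort_index()
                .to_numpy()
            )
            r_pred[method] = _r(n_i, mean_p)

    edges = [1, 2, 3, 4, 5, np.inf]
    labels = ["1", "2", "3", "4", "5+"]
    rows = []
    for k, lab in enumerate(labels):
        mask = (n_i >= edges[k]) & (n_i < edges[k + 1])
        rows.append(
            {
                "discharges": lab,
                "n_patients": int(mask.sum()),
                "pct_readmitted": float(100 * prop[mask].mean()) if mask.any() else float("nan"),
            }
        )

    return DischargeCorrelations(
        r_count=_r(n_i, count),
        r_log_count=_r(np.log(n_i), count),
        r_predicted=r_pred,
        r_log_risk=_r(np.log(n_i), prop),
        bin_table=pd.DataFrame(rows),
    )


def plot_study(result: StudyResult, out_dir: str | Path, cohort: pd.DataFrame | None = None):
    """One line chart per metric (x = cohort size, one series per method).

    When ``cohort`` is given, a bar chart of readmission percent by
    discharge-count bin is added.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    nice = {
        "auc": "C statistic (AUC)",
        "correlation": "Correlation of outcome and prediction",
        "coef_discrimination": "Coefficient of discrimination D",
        "brier": "Brier score",
        "scaled_brier": "Scaled Brier score",
    }
    for metric in METRICS:
        wide = result.pivot(metric)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for method in wide.columns:
            ax.plot(wide.index, wide[method], marker="o", label=method)
        ax.set_xlabel("Cohort size (patients)")
        ax.set_ylabel(nice[metric])
        ax.legend()
        fig.tight_layout()
        path = out / f"{metric}_vs_size.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if cohort is not None:
        corr = discharge_correlations(cohort)
        fig, ax = plt.subplots(figsize=(6, 4))
        tab = corr.bin_table
        ax.bar(tab["discharges"], tab["pct_readmitted"], color="#4878d0")
        ax.set_xlabel("Discharges per patient")
        ax.set_ylabel("% of discharges readmitted")
        ax.set_title(f"r(log discharges, readmission risk) = {corr.r_log_risk:.2f}")
        fig.tight_layout()
        path = out / "readmission_by_discharge_count.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
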