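"""The five model-performance measures for binary risk predictions.

For an outcome vector Y and predicted probabilities p-hat:

* C statistic (AUC) — probability a random event outranks a random
  non-event, Mann-Whitney formulation with ties counted 1/2;
* correlation — Pearson (point-biserial) correlation between Y and p-hat;
* coefficient of discrimination D — |mean p-hat among events - mean p-hat
  among non-events|;
* Brier score — mean squared deviation between p-hat and Y;
* scaled Brier score — 1 - Brier / Brier_max with
  Brier_max = mean(p) * (1 - mean(p)).

By default mean(p) in Brier_max is the observed outcome incidence of the
evaluation sample (for a calibrated model mean p-hat is close to the
incidence); ``brier_max_convention="mean_prediction"`` switches to mean
p-hat.  A metric that is undefined on the given sample (single outcome
class, zero-variance predictions) is returned as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .estimators import FitResult, predict_probability


def _as_arrays(outcomes, predictions) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise ValueError("outcomes and predictions must have equal length")
    if len(y) == 0:
        raise ValueError("empty evaluation sample")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcomes must be binary 0/1")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    return y, p


def c_statistic(outcomes, predictions) -> float:
    """Area under the ROC curve; NaN when only one class is present."""
    y, p = _as_arrays(outcomes, predictions)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, p))


def outcome_correlation(outcomes, predictions) -> float:
    """Pearson correlation between outcome and prediction; NaN if degenerate."""
    y, p = _as_arrays(outcomes, predictions)
    if y.std() == 0 or p.std() == 0:
        return float("nan")
    return float(np.corrcoef(y, p)[0, 1])


def coefficient_of_discrimination(outcomes, predictions) -> float:
    """|mean p-hat over events - mean p-hat over non-events|; NaN if one class."""
    y, p = _as_arrays(outcomes, predictions)
    if y.min() == y.max():
        return float("nan")
    return float(abs(p[y == 1].mean() - p[y == 0].mean()))


def brier_score(outcomes, predictions) -> float:
    """Mean squared deviation between predictions and outcomes."""
    y, p = _as_arrays(outcomes, predictions)
    return float(np.mean((p - y) ** 2))


def brier_max(outcomes, predictions, convention: str = "incidence") -> float:
    """Brier score of the noninformative model, mean(p) * (1 - mean(p))."""
    y, p = _as_arrays(outcomes, predictions)
    if convention == "incidence":
        m = y.mean()
    elif convention == "mean_prediction":
        m = p.mean()
    else:
        raise ValueError(f"unknown brier_max convention {convention!r}")
    return float(m * (1.0 - m))


def scaled_brier(outcomes, predictions, convention: str = "incidence") -> float:
    """1 - Brier / Brier_max; can be negative for worse-than-baseline models.

    NaN when Brier_max is 0 (single-class sample under the incidence
    convention).
    """
    bmax = brier_max(outcomes, predictions, convention)
    if bmax == 0:
        return float("nan")
    return 1.0 - brier_score(outcomes, predictions) / bmax


@dataclass
class PerformanceReport:
    """All five measures plus the observed incidence for one evaluation."""

    auc: float
    correlation: float
    coef_discrimination: float
    brier: float
    brier_max: float
    scaled_brier: float
    observed_rate: float
    n: int

    METRICS = ("auc", "correlation", "coef_discrimination", "brier", "scaled_brier")

    def to_row(self, **keys) -> dict:
        """One flat dict (e.g. a CSV row) with optional identifying keys."""
        row = dict(keys)
        row.update(
            auc=self.auc,
            correlation=self.correlation,
            coef_discrimination=self.coef_discrimination,
            brier=self.brier,
            brier_max=self.brier_max,
            scaled_brier=self.scaled_brier,
            observed_rate=self.observed_rate,
            n=self.n,
        )
        return row


def report(outcomes, predictions, convention: str = "incidence") -> PerformanceReport:
    """Assemble all five measures for one (Y, p-hat) sample."""
    y, p = _as_arrays(outcomes, predictions)
    return PerformanceReport(
        auc=c_statistic(y, p),
        correlation=outcome_correlation(y, p),
        coef_discrimination=coefficient_of_discrimination(y, p),
        brier=brier_score(y, p),
        brier_max=brier_max(y, p, convention),
        scaled_brier=scaled_brier(y, p, convention),
        observed_rate=float(y.mean()),
        n=len(y),
    )


def evaluate(
    fit: FitResult, validation: pd.DataFrame, convention: str = "incidence"
) -> PerformanceReport:
    """Score a fitted model on a validation discharge table.

    The caller chooses the evaluation frame (first discharges or all
    discharges) to match the model's sampling strategy; this function
    simply predicts on the rows it is given.
    """
    p = predict_probability(fit, validation)
    return report(validation["outcome"].to_numpy(), p, convention)
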