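"""Two-stage variable selection: univariate screen, then best subset.

Stage 1 fits a one-covariate model per candidate (with the same estimator
family that will be used for the final model) and keeps candidates with a
Wald p-value below 0.1.  Stage 2 chooses among subsets of the screened
covariates by an information criterion — AIC for ordinary logistic
regression, QIC for GEE/CWGEE — enumerating all subsets when at most 15
covariates survive screening and falling back to forward search otherwise.
Finally, covariates not significant at 0.05 in the multivariable model are
pruned backward (worst first) until every retained covariate is
significant.

Inference throughout uses the cluster-robust (sandwich) standard errors,
which for plain logistic regression on all discharges means the
cluster-robust rather than naive SEs; this is switchable per call.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    ClampedCorrelationWarning,
    FitResult,
    ModelSpec,
    RankDeficientError,
    fit_cwgee,
    fit_gee,
    fit_logistic,
    wald_inference,
)

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 15


def _fit(table: pd.DataFrame, method: str, names: list[str]) -> FitResult:
    spec = ModelSpec(method=method, covariate_names=list(names))
    # candidate fits routinely clamp rho at 0; the clamp is recorded on the
    # FitResult, so the per-fit warning is noise during enumeration
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampedCorrelationWarning)
        if method == "LR":
            return fit_logistic(table, spec)
        if method == "GEE":
            return fit_gee(table, spec)
        if method == "CWGEE":
            return fit_cwgee(table, spec)
    raise ValueError(f"unknown method {method!r}")


def quasi_loglik(fit: FitResult, table: pd.DataFrame) -> float:
    """Bernoulli quasi-likelihood at the fit, with the fit's cluster weights."""
    from .estimators import predict_probability

    mu = np.clip(predict_probability(fit, table), 1e-12, 1 - 1e-12)
    y = table["outcome"].to_numpy(dtype=float)
    ll = y * np.log(mu) + (1.0 - y) * np.log1p(-mu)
    if fit.cluster_weights is not None:
        w = fit.cluster_weights.loc[table["patient_id"]].to_numpy()
        ll = ll * w
    return float(ll.sum())


def information_criterion(fit: FitResult, table: pd.DataFrame) -> float:
    """AIC for LR; QIC (independence quasi-likelihood form) for GEE/CWGEE.

    QIC = -2 Q + 2 trace(Omega_I^{-1} V_R) where Omega_I is the
    independence-model information at the estimate and V_R the robust
    covariance; for LR the trace term reduces to the parameter count and
    the criterion is the ordinary AIC.
    """
    q = quasi_loglik(fit, table)
    if fit.spec.method == "LR":
        penalty = len(fit.params)
    else:
        from .estimators import predict_probability

        names = fit.spec.covariate_names
        sub = table.sort_values("patient_id", kind="stable")
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in names]
        )
        mu = predict_probability(fit, sub)
        a = mu * (1.0 - mu)
        if fit.cluster_weights is not None:
            a = a * fit.cluster_weights.loc[sub["patient_id"]].to_numpy()
        omega = (X * a[:, None]).T @ X
        penalty = float(np.trace(omega @ fit.robust_covariance))
    return -2.0 * q + 2.0 * penalty


@dataclass
class ScreenResult:
    """Outcome of the univariate screen: kept names plus a per-candidate trace."""

    selected: list[str]
    details: pd.DataFrame  # candidate, p, converged, kept, reason

    def __iter__(self):
        return iter(self.selected)


def univariate_screen(
    train: pd.DataFrame,
    candidates: list[str],
    method: str = "LR",
    alpha: float = 0.1,
    covariance: str = "robust",
) -> ScreenResult:
    """Keep candidates whose one-covariate Wald p-value is below ``alpha``.

    Output order equals input order.  A candidate whose fit fails or does
    not converge is excluded with an explicit reason in ``details``.
    """
    missing = [c for c in candidates if c not in train.columns]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    rows, selected = [], []
    for name in candidates:
        reason, pval, ok, conv = "", float("nan"), False, False
        try:
            fit = _fit(train, method, [name])
            conv = fit.converged
            if not conv:
                reason = f"fit did not converge: {fit.message}"
            else:
                pval = float(wald_inference(fit, covariance)["p"].iloc[1])
                ok = pval < alpha
                if not ok:
                    reason = f"p = {pval:.4g} >= {alpha}"
        except (RankDeficientError, np.linalg.LinAlgError, ValueError) as exc:
            reason = f"fit failed: {exc}"
        if ok:
            selected.append(name)
        rows.append(
            {"candidate": name, "p": pval, "converged": conv, "kept": ok, "reason": reason}
        )
        logger.debug("screen %-12s p=%-10.4g kept=%s %s", name, pval, ok, reason)
    details = pd.DataFrame(rows)
    return ScreenResult(selected=selected, details=details)


@dataclass
class SelectionResult:
    """Final model after best-subset choice and backward pruning."""

    spec: ModelSpec
    fit: FitResult
    criterion: float
    trace: list[dict] = field(default_factory=list)  # subset scores and pruning steps
    notes: list[str] = field(default_factory=list)


def _criterion_of(train, method, names) -> tuple[float, FitResult | None, str]:
    try:
        fit = _fit(train, method, list(names))
    except (RankDeficientError, np.linalg.LinAlgError, ValueError) as exc:
        return float("inf"), None, f"{exc}"
    if not fit.converged:
        return float("inf"), fit, f"not converged: {fit.message}"
    return information_criterion(fit, train), fit, ""


def best_subset_select(
    train: pd.DataFrame,
    screened: list[str],
    method: str = "LR",
    alpha: float = 0.05,
    covariance: str = "robust",
) -> SelectionResult:
    """Best-subset selection followed by backward pruning at ``alpha``.

    All 2^p subsets (including the intercept-only model) are scored by
    AIC/QIC when p <= 15; beyond that, forward search adds the covariate
    with the best criterion improvement until no addition improves it.
    Pruning then drops, one at a time, the covariate with the largest
    p >= alpha (ties: the one with smaller |z| is dropped, then later
    lexical name order) and refits.  Deterministic given its input.
    """
    if not screened:
        raise ValueError("screened covariate list is empty")
    trace: list[dict] = []
    notes: list[str] = []

    if len(screened) <= EXHAUSTIVE_LIMIT:
        best_names, best_crit, best_fit = (), float("inf"), None
        for k in range(len(screened) + 1):
            for names in itertools.combinations(screened, k):
                crit, fit, reason = _criterion_of(train, method, names)
                trace.append({"step": "subset", "covariates": list(names), "criterion": crit, "reason": reason})
                if reason and fit is None:
                    continue
                if crit < best_crit:
                    best_names, best_crit, best_fit = names, crit, fit
    else:
        notes.append(
            f"{len(screened)} screened covariates > {EXHAUSTIVE_LIMIT}; forward search used"
        )
        current: list[str] = []
        best_crit, best_fit, _ = _criterion_of(train, method, current)
        trace.append({"step": "forward", "covariates": [], "criterion": best_crit, "reason": ""})
        improved = True
        while improved:
            improved = False
            best_add, add_crit, add_fit = None, best_crit, None
            for name in screened:
                if name in current:
                    continue
                crit, fit, reason = _criterion_of(train, method, current + [name])
                trace.append({"step": "forward", "covariates": current + [name], "criterion": crit, "reason": reason})
                if crit < add_crit:
                    best_add, add_crit, add_fit = name, crit, fit
            if best_add is not None:
                current.append(best_add)
                best_crit, best_fit, improved = add_crit, add_fit, True
        best_names = tuple(current)

    if best_fit is None:
        raise RuntimeError("no candidate subset produced a usable fit")

    # collinear subsets score +inf above, so at most one of a collinear
    # pair can appear in the winner; note when that pruning was exercised
    if any(t["reason"] and "rank deficient" in t["reason"] for t in trace):
        notes.append("rank-deficient subsets excluded (collinear candidates)")

    # backward pruning at alpha on the multivariable fit
    names = list(best_names)
    fit = best_fit
    while names:
        wt = wald_inference(fit, covariance).iloc[1:]  # drop intercept row
        insig = wt[wt["p"] >= alpha]
        if insig.empty:
            break
        # drop the largest p; among ties the smaller |z| goes first, then
        # the lexically later name
        ranked = insig.assign(absz=np.abs(insig["z"])).sort_values(
            ["p", "absz", "term"], ascending=[False, True, False]
        )
        drop = ranked.iloc[0]["term"]
        trace.append({"step": "prune", "covariates": list(names), "criterion": float("nan"), "reason": f"dropped {drop}"})
        names.remove(drop)
        if names:
            fit = _fit(train, method, names)
        else:
            fit = None
            break

    if fit is None:
        fit = _fit(train, method, [])
    if not fit.spec.covariate_names:
        notes.append("intercept-only final model")
    spec = fit.spec
    crit = information_criterion(fit, train)
    return SelectionResult(spec=spec, fit=fit, criterion=crit, trace=trace, notes=notes)
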