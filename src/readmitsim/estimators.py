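"""Marginal logistic models for clustered binary outcomes.

Three estimator families for logit(E[Y|X]) = alpha + beta'X:

* ``fit_logistic`` — ordinary maximum likelihood via iteratively
  reweighted least squares (IRLS), ignoring clustering in the point
  estimates but reporting a cluster-robust sandwich covariance alongside
  the naive inverse-information covariance.
* ``fit_gee`` — generalized estimating equations with an exchangeable (or
  independence) working correlation; the exchangeable parameter rho is
  re-estimated each outer iteration by a moment estimator on Pearson
  residuals.  Optional per-cluster weights multiply each cluster's whole
  contribution to the estimating function, the bread and the meat.
* ``fit_cwgee`` — cluster-weighted GEE: identical machinery with weights
  w_i = 1/n_i, which re-targets estimation at the per-patient (rather than
  per-discharge) marginal and is valid under informative cluster size.

The exchangeable working correlation R = (1-rho) I + rho J admits the
closed-form inverse R^{-1} v = [v - c_n (sum v) 1] / (1 - rho) with
c_n = rho / (1 + (n-1) rho), which the solver exploits so every quantity
is computed by grouped vector operations rather than per-cluster matrix
inversions.

The rho moment estimator follows the standard convention: the sum of
within-cluster pairwise products of Pearson residuals, divided by the
estimated scale, over (number of pairs - p), with scale = sum r^2 / (N - p)
where p counts regression parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .table_io import covariate_columns, validate_discharge_table

DEFAULT_TOL = 1e-8
DEFAULT_MAXITER = 100
#: Working-correlation bounds; moment estimates outside are clamped with a
#: warning.  Pass wider bounds (e.g. (-0.99, 0.99)) to allow negative
#: exchangeable correlation.
DEFAULT_RHO_BOUNDS = (0.0, 0.99)

#: Variance floor keeping Pearson residuals finite when a diverging
#: candidate fit pushes mu to the 0/1 boundary.
_VAR_FLOOR = 1e-12


class ClampedCorrelationWarning(RuntimeWarning):
    """The exchangeable moment estimate fell outside the allowed bounds."""


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")


class SeparationError(RuntimeError):
    """Perfect separation: the likelihood has no finite maximizer."""


@dataclass
class ModelSpec:
    """What to fit: estimator family, covariates and working correlation."""

    method: str = "LR"  # LR | GEE | CWGEE
    covariate_names: list[str] = field(default_factory=list)
    correlation: str | None = None  # independence | exchangeable
    link: str = "logit"

    def __post_init__(self) -> None:
        if self.method not in {"LR", "GEE", "CWGEE"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.link != "logit":
            raise ValueError("only the logit link is supported")
        if self.correlation is None:
            self.correlation = "independence" if self.method == "LR" else "exchangeable"
        if self.method == "LR" and self.correlation != "independence":
            raise ValueError("LR implies an independence structure")
        if self.correlation not in {"independence", "exchangeable"}:
            raise ValueError(f"unknown correlation structure {self.correlation!r}")


@dataclass
class FitResult:
    """One fitted marginal model with naive and robust inference."""

    spec: ModelSpec
    intercept: float
    coefficients: np.ndarray  # aligned with spec.covariate_names
    naive_covariance: np.ndarray  # (p+1, p+1), intercept first
    robust_covariance: np.ndarray
    working_correlation: float  # rho-hat; 0.0 for LR / independence
    cluster_weights: pd.Series | None  # per-cluster weights (None = all 1)
    converged: bool
    n_iterations: int
    n_obs: int
    n_clusters: int
    score_norm: float  # max-norm of the estimating function at the estimate
    scale: float = 1.0
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])

    @property
    def param_names(self) -> list[str]:
        return ["(intercept)"] + list(self.spec.covariate_names)

    def to_dict(self) -> dict:
        """Plain-JSON report of the fit."""
        robust_se = np.sqrt(np.diag(self.robust_covariance))
        naive_se = np.sqrt(np.diag(self.naive_covariance))
        return {
            "method": self.spec.method,
            "correlation": self.spec.correlation,
            "terms": self.param_names,
            "estimates": self.params.tolist(),
            "naive_se": naive_se.tolist(),
            "robust_se": robust_se.tolist(),
            "working_correlation": self.working_correlation,
            "cluster_weights": (
                None
                if self.cluster_weights is None
                else {
                    "min": float(self.cluster_weights.min()),
                    "max": float(self.cluster_weights.max()),
                    "mean": float(self.cluster_weights.mean()),
                }
            ),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "score_norm": self.score_norm,
            "message": self.message,
        }


def _design(table: pd.DataFrame, names: list[str] | None):
    validate_discharge_table(table)
    if names is None:
        names = covariate_columns(table)
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise KeyError(f"covariates not in table: {missing}")
    # contiguous cluster blocks; stable sort keeps within-cluster order
    table = table.sort_values("patient_id", kind="stable")
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in names]
    )
    y = table["outcome"].to_numpy(dtype=float)
    ids = table["patient_id"].to_numpy()
    _, starts, sizes = np.unique(ids, return_index=True, return_counts=True)
    cluster_ids = ids[starts]
    return X, y, names, starts, sizes, cluster_ids


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted QR names the columns that add (numerically) no rank
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    if len(bad):
        labels = ["(intercept)"] + list(names)
        raise RankDeficientError([labels[j] for j in sorted(bad)])


def fit_logistic(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAXITER,
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Clusters (patient_id) are used only for the robust sandwich
    covariance.  Perfect separation is flagged through ``converged=False``
    and ``message`` rather than silently returning a diverging estimate.
    """
    if spec is None:
        spec = ModelSpec(method="LR", covariate_names=covariate_columns(table))
    X, y, names, starts, sizes, cluster_ids = _design(table, spec.covariate_names)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    _check_rank(X, names)

    p = X.shape[1]
    beta = np.zeros(p)
    converged, it = False, 0
    message = ""
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation)"
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if converged and np.max(np.abs(beta)) > 30:
        converged = False
        message = "diverging coefficients suggest perfect separation"
    elif not converged and not message:
        message = f"IRLS did not converge in {max_iter} iterations"

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        naive = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # saturated fit (separation): report the pseudo-inverse, flagged
        naive = np.linalg.pinv(info)
        converged = False
        message = message or "singular information at the returned estimate"
    resid_x = X * (y - mu)[:, None]
    scores_i = np.add.reduceat(resid_x, starts, axis=0)  # per-cluster scores
    meat = scores_i.T @ scores_i
    robust = naive @ meat @ naive

    return FitResult(
        spec=spec,
        intercept=beta[0],
        coefficients=beta[1:],
        naive_covariance=naive,
        robust_covariance=robust,
        working_correlation=0.0,
        cluster_weights=None,
        converged=converged,
        n_iterations=it,
        n_obs=len(y),
        n_clusters=len(starts),
        score_norm=float(np.max(np.abs(X.T @ (y - mu)))),
        message=message,
    )


def _estimate_rho(
    r: np.ndarray, starts: np.ndarray, sizes: np.ndarray, w: np.ndarray, p: int
) -> tuple[float, float]:
    """Moment estimator of the exchangeable correlation and the scale.

    ``r`` are Pearson residuals, ``w`` per-cluster weights.  Both the
    scale and the pairwise-product denominator carry the (N - p)-type
    degrees-of-freedom correction.
    """
    nobs = len(r)
    ssr = np.add.reduceat(r * r, starts)
    rsum = np.add.reduceat(r, starts)
    pair_prod = (rsum**2 - ssr) / 2.0
    npr = sizes * (sizes - 1) / 2.0

    fsum1 = float(np.sum(w * sizes))
    scale = float(np.sum(w * ssr)) / (fsum1 * (nobs - p) / nobs)
    n_pairs = float(np.sum(npr))
    fsum2 = float(np.sum(w * npr))
    if n_pairs <= p or fsum2 == 0:
        return 0.0, scale
    rho = float(np.sum(w * pair_prod)) / scale / (fsum2 * (n_pairs - p) / n_pairs)
    return rho, scale


def fit_gee(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    weights: pd.Series | dict | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAXITER,
    rho_bounds: tuple[float, float] = DEFAULT_RHO_BOUNDS,
) -> FitResult:
    """Solve the weighted GEE sum_i w_i D_i' V_i^{-1} (Y_i - mu_i) = 0.

    Fisher-scoring updates alternate with re-estimation of the
    exchangeable rho until the max coefficient update drops below ``tol``.
    The fit is initialized at the independence (logistic) solution.  The
    sandwich covariance applies the same cluster weights in bread and
    meat; the naive covariance is the scale-multiplied bread inverse.
    """
    if spec is None:
        spec = ModelSpec(method="GEE", covariate_names=covariate_columns(table))
    X, y, names, starts, sizes, cluster_ids = _design(table, spec.covariate_names)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    _check_rank(X, names)
    p = X.shape[1]

    if weights is None:
        w = np.ones(len(starts))
    else:
        wser = pd.Series(weights)
        try:
            w = wser.loc[cluster_ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise KeyError(f"missing cluster weight: {exc}") from exc
        if np.any(w <= 0):
            raise ValueError("cluster weights must be positive")
    w_row = np.repeat(w, sizes)

    init = fit_logistic(table, ModelSpec(method="LR", covariate_names=list(names)))
    beta = init.params.copy()

    exchangeable = spec.correlation == "exchangeable"
    rho, scale = 0.0, 1.0
    clamped = False
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        a = np.clip(mu * (1.0 - mu), _VAR_FLOOR, None)
        s = np.sqrt(a)
        r = (y - mu) / s

        if exchangeable:
            rho_raw, scale = _estimate_rho(r, starts, sizes, w, p)
            rho = float(np.clip(rho_raw, *rho_bounds))
            if rho != rho_raw:
                clamped = True

        c = rho / (1.0 + (sizes - 1.0) * rho)  # per-cluster off-diag factor

        sx = X * s[:, None]
        T = np.add.reduceat(sx, starts, axis=0)  # per-cluster sum of s*x
        rsum = np.add.reduceat(r, starts)
        # H = sum_i w_i X_i' S R^{-1} S X_i ; g = sum_i w_i X_i' S R^{-1} r_i
        H = ((sx * w_row[:, None]).T @ sx - (T * (w * c)[:, None]).T @ T) / (1.0 - rho)
        g_rows = sx * r[:, None]
        g = ((g_rows * w_row[:, None]).sum(axis=0) - ((w * c * rsum)[:, None] * T).sum(axis=0)) / (
            1.0 - rho
        )
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return _flagged_result(
                spec, beta, p, w, cluster_ids, len(y), len(starts),
                "singular working information", it, rho, scale,
            )
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    # final quantities at the returned estimate
    mu = expit(X @ beta)
    a = np.clip(mu * (1.0 - mu), _VAR_FLOOR, None)
    s = np.sqrt(a)
    r = (y - mu) / s
    c = rho / (1.0 + (sizes - 1.0) * rho)
    sx = X * s[:, None]
    T = np.add.reduceat(sx, starts, axis=0)
    rsum = np.add.reduceat(r, starts)
    H = ((sx * w_row[:, None]).T @ sx - (T * (w * c)[:, None]).T @ T) / (1.0 - rho)
    g_i = (np.add.reduceat(sx * r[:, None], starts, axis=0) - (c * rsum)[:, None] * T) / (
        1.0 - rho
    )
    g_i = g_i * w[:, None]
    score = g_i.sum(axis=0)

    bread = np.linalg.inv(H)
    meat = g_i.T @ g_i
    robust = bread @ meat @ bread
    naive = scale * bread

    message = ""
    if clamped:
        message = f"working correlation clamped to {rho_bounds}"
        warnings.warn(
            f"exchangeable correlation estimate clamped to {rho_bounds}",
            ClampedCorrelationWarning,
            stacklevel=2,
        )
    if not converged:
        message = (message + "; " if message else "") + (
            f"GEE did not converge in {max_iter} iterations"
        )

    cluster_weights = None
    if weights is not None:
        cluster_weights = pd.Series(w, index=pd.Index(cluster_ids, name="patient_id"))

    return FitResult(
        spec=spec,
        intercept=beta[0],
        coefficients=beta[1:],
        naive_covariance=naive,
        robust_covariance=robust,
        working_correlation=float(rho),
        cluster_weights=cluster_weights,
        converged=converged,
        n_iterations=it,
        n_obs=len(y),
        n_clusters=len(starts),
        score_norm=float(np.max(np.abs(score))),
        scale=float(scale),
        message=message,
    )


def _flagged_result(spec, beta, p, w, cluster_ids, n_obs, n_clusters, msg, it, rho, scale):
    nanmat = np.full((p, p), np.nan)
    return FitResult(
        spec=spec,
        intercept=beta[0],
        coefficients=beta[1:],
        naive_covariance=nanmat,
        robust_covariance=nanmat,
        working_correlation=float(rho),
        cluster_weights=pd.Series(w, index=pd.Index(cluster_ids, name="patient_id")),
        converged=False,
        n_iterations=it,
        n_obs=n_obs,
        n_clusters=n_clusters,
        score_norm=float("nan"),
        scale=float(scale),
        message=msg,
    )


def fit_cwgee(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAXITER,
    rho_bounds: tuple[float, float] = DEFAULT_RHO_BOUNDS,
) -> FitResult:
    """Cluster-weighted GEE: the GEE of :func:`fit_gee` with w_i = 1/n_i.

    Weighting each cluster inversely to its size removes the over-
    representation of large (sicker, more frequently readmitted) clusters,
    giving consistent estimation of the per-patient marginal model when
    cluster size is informative.
    """
    if spec is None:
        spec = ModelSpec(method="CWGEE", covariate_names=covariate_columns(table))
    validate_discharge_table(table)
    sizes = table.groupby("patient_id", sort=True).size()
    weights = 1.0 / sizes
    return fit_gee(
        table, spec, weights=weights, tol=tol, max_iter=max_iter, rho_bounds=rho_bounds
    )


def predict_probability(fit: FitResult, covariates) -> np.ndarray:
    """Predicted readmission probability expit(alpha + beta'x), overflow-safe.

    ``covariates`` may be a discharge table / DataFrame containing the
    fit's covariate columns, or an array with one column per covariate.
    """
    names = fit.spec.covariate_names
    if isinstance(covariates, pd.DataFrame):
        missing = [c for c in names if c not in covariates.columns]
        if missing:
            raise KeyError(f"covariates not in table: {missing}")
        X = covariates[names].to_numpy(dtype=float) if names else np.empty((len(covariates), 0))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != len(names):
            raise ValueError(f"expected {len(names)} covariates, got {X.shape[1]}")
    eta = fit.intercept + X @ fit.coefficients
    return expit(eta)


def wald_inference(fit: FitResult, covariance: str = "robust") -> pd.DataFrame:
    """Per-coefficient Wald table: estimate, SE, z and two-sided p-value.

    ``covariance`` selects the robust (sandwich, default) or naive SEs.
    p-values use the standard-normal reference for z = estimate / SE.
    """
    cov = fit.robust_covariance if covariance == "robust" else fit.naive_covariance
    se = np.sqrt(np.diag(cov))
    est = fit.params
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": fit.param_names, "estimate": est, "se": se, "z": z, "p": pval}
    )
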