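"""Logistic-regression estimators for the three analysis strategies.

Three ways of analyzing a sample whose strata were built from a possibly
misclassified category:

* *design-agnostic*: ordinary ML logistic regression of the outcome on the
  true-category dummies and extra covariates, ignoring the design;
* *model-based*: the same, additionally adjusting for the recorded-category
  dummies (the sampling variable enters as a covariate);
* *design-based*: weighted pseudo-maximum-likelihood, maximizing
  sum_i w_i { y_i log p_i + (1 - y_i) log(1 - p_i) } with the inverse
  selection-probability weights, variance by Taylor linearization
  (sandwich).

The fitter is iteratively reweighted least squares with step-halving so the
(weighted) log-likelihood never decreases; convergence is declared when the
relative deviance change drops below 1e-8 (at most 25 iterations) — the
stopping rule R's glm uses, so separated fits plateau at the same values
R reports.  Only coefficients diverging past |30| on the log-odds scale
are flagged non-converged; nothing is raised for separation.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit
from scipy.stats import norm

from .popgen import Population, dummies
from .sampling import SurveySample

logger = logging.getLogger(__name__)

MAX_ITER = 25
DEVIANCE_RTOL = 1e-8
# Fits whose deviance plateaus but whose coefficients have drifted past this
# magnitude are flagged as separated.  Deviance-converged fits with a
# zero-success cell of a few dozen units plateau near |beta| ~ 15 (as R's glm
# does, reporting them converged), so the flag is set well beyond that: only
# genuinely diverging fits are excluded from Monte-Carlo summaries.
SEPARATION_THRESHOLD = 30.0
_PCLIP = 1e-12

METHODS = ("design_agnostic", "model_based", "design_based")


class SingularDesignError(ValueError):
    pass


class SingleUnitStratumError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which analysis strategy to fit and how to compute its variance.

    ``variance`` only matters for the design-based method: "unstratified"
    treats weighted units as independent (with-replacement approximation);
    "stratified" centers score contributions within sampling strata and
    applies the n_h / (n_h - 1) factor.
    """

    method: str
    ci_level: float = 0.95
    variance: str = "unstratified"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.variance not in ("unstratified", "stratified"):
            raise ValueError(f"unknown variance form {self.variance!r}")


@dataclasses.dataclass
class FitResult:
    """One fitted model: point estimates, variance, Wald intervals, diagnostics."""

    coefficients: pd.Series
    vcov: pd.DataFrame
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    converged: bool
    n_iterations: int
    log_likelihood: float
    variance_method: str
    ci_level: float = 0.95
    dropped_terms: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.to_dict(),
                "se": self.se.to_dict(),
                "ci_lower": self.ci_lower.to_dict(),
                "ci_upper": self.ci_upper.to_dict(),
                "converged": bool(self.converged),
                "n_iterations": int(self.n_iterations),
                "log_likelihood": float(self.log_likelihood),
                "variance_method": self.variance_method,
                "ci_level": self.ci_level,
                "dropped_terms": list(self.dropped_terms),
            },
            indent=2,
        )

    def to_csv_row(self, scenario: str = "", method: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": scenario,
                "method": method,
                "parameter": self.coefficients.index,
                "estimate": self.coefficients.to_numpy(),
                "se": self.se.to_numpy(),
                "ci_lower": self.ci_lower.to_numpy(),
                "ci_upper": self.ci_upper.to_numpy(),
                "converged": self.converged,
            }
        )


def _as_matrix(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(float), [str(c) for c in design.columns]
    X = np.asarray(design, float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # column-pivoted QR flags the specific offending columns
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = piv[np.flatnonzero(diag <= tol)]
    if len(bad) or diag.size < X.shape[1]:
        cols = ", ".join(names[j] for j in sorted(bad))
        raise SingularDesignError(f"design matrix is rank deficient (columns: {cols})")


def _loglik(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def fit_logistic(
    y: np.ndarray,
    design,
    weights: np.ndarray | None = None,
    ci_level: float = 0.95,
    max_iter: int = MAX_ITER,
    tol: float = DEVIANCE_RTOL,
) -> FitResult:
    """Maximize the (weighted) Bernoulli log-likelihood by IRLS.

    ``design`` must include the intercept column.  With ``weights`` the
    objective is the weighted pseudo-log-likelihood; point estimates are
    invariant to rescaling the weights.  The returned variance is the
    inverse observed information (model-based); callers wanting a sandwich
    replace it via :func:`variance_sandwich`.
    """
    X, names = _as_matrix(design)
    y = np.asarray(y, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and design have different lengths")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _loglik(y, eta, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        wls = w * p * (1 - p)
        z = eta + (y - p) / (p * (1 - p))
        XtW = X.T * wls
        try:
            step_target = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:  # weights collapsed a column
            raise SingularDesignError(str(exc)) from exc
        # step-halving: never let the objective decrease
        new_beta = step_target
        new_eta = X @ new_beta
        new_ll = _loglik(y, new_eta, w)
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 10:
            new_beta = 0.5 * (new_beta + beta)
            new_eta = X @ new_beta
            new_ll = _loglik(y, new_eta, w)
            halvings += 1
        beta, eta = new_beta, new_eta
        if abs(new_ll - ll) / (abs(new_ll) + 0.1) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if converged and np.max(np.abs(beta)) > SEPARATION_THRESHOLD:
        converged = False  # likely separation: estimates diverging

    coefficients = pd.Series(beta, index=names)
    vcov = variance_model_based(coefficients, X, None if weights is None else w)
    return _package(coefficients, vcov, "model_based_information", converged, it, ll,
                    ci_level)


def _package(
    coefficients: pd.Series,
    vcov: np.ndarray,
    variance_method: str,
    converged: bool,
    n_iter: int,
    ll: float,
    ci_level: float,
    dropped: tuple[str, ...] = (),
) -> FitResult:
    names = list(coefficients.index)
    se = pd.Series(np.sqrt(np.diag(vcov)), index=names)
    z = norm.ppf(0.5 + ci_level / 2)
    return FitResult(
        coefficients=coefficients,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        se=se,
        ci_lower=coefficients - z * se,
        ci_upper=coefficients + z * se,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll,
        variance_method=variance_method,
        ci_level=ci_level,
        dropped_terms=dropped,
    )


def _mu(coefficients, X: np.ndarray) -> np.ndarray:
    beta = coefficients.to_numpy() if isinstance(coefficients, pd.Series) else np.asarray(coefficients)
    return np.clip(expit(X @ beta), _PCLIP, 1 - _PCLIP)


def variance_model_based(fit, design, weights: np.ndarray | None = None) -> np.ndarray:
    """Inverse of the negative Hessian of the (weighted) log-likelihood."""
    X, _ = _as_matrix(design)
    coefficients = fit.coefficients if isinstance(fit, FitResult) else fit
    p = _mu(coefficients, X)
    w = np.ones(X.shape[0]) if weights is None else np.asarray(weights, float)
    A = (X.T * (w * p * (1 - p))) @ X
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"singular Hessian: {exc}") from exc


def variance_sandwich(
    fit,
    y: np.ndarray,
    design,
    weights: np.ndarray,
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """Linearization variance A^-1 B A^-1 for the weighted pseudo-ML fit.

    ``A`` is the negative Hessian of the weighted log-likelihood; ``B``
    measures the variability of the weighted score contributions
    ``u_i = w_i (y_i - p_i) x_i``.  Unstratified form: ``B = sum u_i u_i^T``
    (independent weighted units).  Stratified form: scores are centered
    within each stratum and scaled by ``n_h / (n_h - 1)``, the
    with-replacement approximation used by survey software.
    """
    X, _ = _as_matrix(design)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    coefficients = fit.coefficients if isinstance(fit, FitResult) else fit
    p = _mu(coefficients, X)
    A = (X.T * (w * p * (1 - p))) @ X
    U = (w * (y - p))[:, None] * X
    if strata is None:
        B = U.T @ U
    else:
        strata = np.asarray(strata)
        B = np.zeros((X.shape[1], X.shape[1]))
        for h in np.unique(strata):
            idx = strata == h
            n_h = int(idx.sum())
            if n_h < 2:
                raise SingleUnitStratumError(
                    f"stratum {h} has a single sampled unit; "
                    "use the unstratified variance instead"
                )
            Uc = U[idx] - U[idx].mean(axis=0)
            B += (n_h / (n_h - 1)) * (Uc.T @ Uc)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def _design_frame(
    pop: Population,
    rows: np.ndarray | None,
    include_recorded: bool,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, names) for the requested units (all if rows is None)."""
    sel = slice(None) if rows is None else rows
    X_true = pop.X[sel]
    L = pop.low_income[sel]
    y = pop.Y[sel]
    cols = [np.ones(len(y))]
    names = ["intercept"]
    cols.append(dummies(X_true, pop.H))
    names += list(pop.labels[1:])
    if include_recorded:
        cols.append(dummies(pop.X_star[sel], pop.H))
        names += [f"recorded_{lab}" for lab in pop.labels[1:]]
    cols.append(L[:, None].astype(float))
    names.append("low_income")
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return y.astype(float), X, names


def _drop_empty(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    # a category absent from the sample yields an all-zero dummy column
    keep = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0)]
    dropped = tuple(names[j] for j in range(X.shape[1]) if j not in keep)
    if dropped:
        logger.info("dropping empty design columns: %s", ", ".join(dropped))
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names, dropped


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Drop later columns that are linear combinations of earlier ones.

    Mirrors R's handling of aliased terms: a sequential (non-pivoted) QR
    flags column j as aliased when its R diagonal is negligible given the
    columns before it.  Without misclassification the recorded-category
    dummies duplicate the true-category dummies exactly and are dropped
    here, reducing the adjusted model to the unadjusted one.
    """
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = (diag.max() if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
    keep = [j for j in range(X.shape[1]) if j < len(diag) and diag[j] > tol]
    if len(keep) == X.shape[1]:
        return X, names, ()
    # QR diagonals are order-sensitive; re-verify greedily so only truly
    # dependent columns go
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept.append(j)
    dropped = tuple(names[j] for j in range(X.shape[1]) if j not in kept)
    logger.info("dropping aliased design columns: %s", ", ".join(dropped))
    return X[:, kept], [names[j] for j in kept], dropped


def _aggregate_cohort(
    pop: Population, include_recorded: bool
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Collapse the cohort into covariate-pattern cells with frequency weights.

    The weighted Bernoulli log-likelihood, score and Hessian with frequency
    weights are identical to the unit-level unweighted ones, so the fit and
    its information-based variance are unchanged; with a handful of discrete
    covariates this turns an N-row IRLS into a <=100-row one.
    """
    H = pop.H
    key = pop.Y + 2 * (pop.low_income + 2 * (pop.X - 1))
    ncell = 4 * H
    if include_recorded:
        key = key + ncell * (pop.X_star - 1)
        ncell *= H
    freq = np.bincount(key, minlength=ncell).astype(float)
    cells = np.flatnonzero(freq > 0)
    y = (cells % 2).astype(float)
    li = (cells // 2) % 2
    x = (cells // 4) % H + 1
    cols = [np.ones(len(cells)), dummies(x, H)]
    names = ["intercept", *pop.labels[1:]]
    if include_recorded:
        xs = cells // (4 * H) + 1
        cols.append(dummies(xs, H))
        names += [f"recorded_{lab}" for lab in pop.labels[1:]]
    cols.append(li[:, None].astype(float))
    names.append("low_income")
    X = np.column_stack([c if c.ndim == 2 else np.asarray(c, float)[:, None] for c in cols])
    return y, X, names, freq[cells]


def fit_method(
    pop: Population,
    sample: SurveySample | None,
    spec: ModelSpec,
) -> FitResult:
    """Fit one analysis strategy to a sample (or to the whole cohort).

    ``sample=None`` fits the model to the full population (ordinary ML; the
    design-based method is meaningless there and is rejected).  Recorded
    categories absent from the sample have their dummies dropped with a
    logged note so the design stays full rank.
    """
    if sample is None:
        if spec.method == "design_based":
            raise ValueError("design_based requires a sample with weights")
        y, X, names, freq = _aggregate_cohort(pop, spec.method == "model_based")
        X, names, dropped = _drop_empty(X, names)
        X, names, aliased = _drop_aliased(X, names)
        dropped += aliased
        fit = fit_logistic(y, pd.DataFrame(X, columns=names), weights=freq,
                           ci_level=spec.ci_level)
        fit.dropped_terms = dropped
        return fit

    rows = sample.unit_ids
    y, X, names = _design_frame(pop, rows, spec.method == "model_based")
    X, names, dropped = _drop_empty(X, names)
    X, names, aliased = _drop_aliased(X, names)
    dropped += aliased
    frame = pd.DataFrame(X, columns=names)

    if spec.method == "design_based":
        fit = fit_logistic(y, frame, weights=sample.weights, ci_level=spec.ci_level)
        strata = sample.stratum if spec.variance == "stratified" else None
        vcov = variance_sandwich(fit, y, X, sample.weights, strata=strata)
        fit = _package(
            fit.coefficients, vcov, "sandwich", fit.converged, fit.n_iterations,
            fit.log_likelihood, spec.ci_level, dropped,
        )
        return fit
    fit = fit_logistic(y, frame, ci_level=spec.ci_level)
    fit.dropped_terms = dropped
    return fit
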