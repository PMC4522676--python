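"""Survival analysis: Kaplan-Meier, log-rank, and Cox proportional hazards.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
Cox regression uses a native Newton-Raphson maximizer of the partial
likelihood with the Efron tie correction and step-halving: the resampling
module fits tens of thousands of univariate models per run, and a lean
vectorized solver keeps that tractable.  The solver is cross-checked against
lifelines and against brute-force partial-likelihood evaluation in the test
suite.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = 1.96  # Wald 95% CI half-width multiplier on the log-hazard scale


class CoxError(RuntimeError):
    """Cox model could not be fit."""


class CoxConvergenceError(CoxError):
    """Newton iterations failed to converge (includes monotone likelihood)."""


# ---------------------------------------------------------------------------
# partial likelihood machinery
# ---------------------------------------------------------------------------

def _prepare(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order].astype(bool)


def partial_loglik(X, time, event, beta) -> float:
    """Efron partial log-likelihood at ``beta`` (exposed for verification)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.size(time):
        X = X.T
    ll, _, _ = _efron_parts(*_prepare(X, np.asarray(time, float), np.asarray(event)),
                            np.atleast_1d(np.asarray(beta, float)))
    return ll


def _efron_parts(X, time, event, beta):
    """(loglik, gradient, hessian) of the Efron-corrected partial likelihood.

    Inputs must be sorted by time ascending.
    """
    n, p = X.shape
    eta = X @ beta
    c = eta.max()
    w = np.exp(eta - c)

    # risk-set sums: S0(t) = sum_{time_i >= t} w_i, similarly S1 (p,), S2 (p,p)
    rc0 = np.cumsum(w[::-1])[::-1]
    rc1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    XX = X[:, :, None] * X[:, None, :]
    rc2 = np.cumsum((XX * w[:, None, None])[::-1], axis=0)[::-1]

    uniq, first = np.unique(time, return_index=True)
    inv = np.searchsorted(uniq, time)
    d = np.bincount(inv, weights=event.astype(float), minlength=len(uniq))
    has_death = d > 0

    ev = event
    ll = float((eta[ev] - c).sum())
    grad = X[ev].sum(axis=0)
    hess = np.zeros((p, p))

    if np.max(d, initial=0.0) <= 1.0:
        # no tied deaths: Efron == Breslow, fully vectorized
        idx = first[has_death]
        S0 = rc0[idx]
        S1 = rc1[idx]
        S2 = rc2[idx]
        ll -= float(np.log(S0).sum())
        grad -= (S1 / S0[:, None]).sum(axis=0)
        mean = S1 / S0[:, None]
        hess -= (S2 / S0[:, None, None]).sum(axis=0)
        hess += np.einsum("ki,kj->ij", mean, mean)
        return ll, grad, hess

    # general tie-aware path
    s0d = np.bincount(inv, weights=ev * w, minlength=len(uniq))
    s1d = np.zeros((len(uniq), p))
    s2d = np.zeros((len(uniq), p, p))
    for j in range(p):
        s1d[:, j] = np.bincount(inv, weights=ev * w * X[:, j], minlength=len(uniq))
        for k in range(j, p):
            col = np.bincount(inv, weights=ev * w * XX[:, j, k], minlength=len(uniq))
            s2d[:, j, k] = col
            s2d[:, k, j] = col
    for u in np.flatnonzero(has_death):
        du = int(d[u])
        S0, S1, S2 = rc0[first[u]], rc1[first[u]], rc2[first[u]]
        for l in range(du):
            f = l / du
            denom = S0 - f * s0d[u]
            num1 = S1 - f * s1d[u]
            num2 = S2 - f * s2d[u]
            ll -= float(np.log(denom))
            grad -= num1 / denom
            hess -= num2 / denom - np.outer(num1, num1) / denom**2
    return ll, grad, hess


def _newton_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
    beta_bound: float = 40.0,
):
    """Maximize the partial likelihood; returns (beta, se, loglik)."""
    X, time, event = _prepare(X, time, event)
    n, p = X.shape
    if not event.any():
        raise CoxError("no events in the data")
    beta = np.zeros(p)
    ll, grad, hess = _efron_parts(X, time, event, beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving on overshoot
        factor = 1.0
        for _half in range(40):
            beta_new = beta + factor * step
            ll_new, grad_new, hess_new = _efron_parts(X, time, event, beta_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            raise CoxConvergenceError("step-halving failed to improve the likelihood")
        converged = abs(ll_new - ll) <= tol * (abs(ll) + tol)
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.abs(beta).max() > beta_bound:
            raise CoxConvergenceError(
                "coefficient diverging: monotone likelihood / complete separation"
            )
        if converged:
            break
    else:
        raise CoxConvergenceError(f"no convergence in {max_iter} iterations")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise CoxConvergenceError("non-positive-definite information at the optimum")
    # a likelihood flattening out at an implausibly large coefficient, or an
    # essentially unbounded standard error, marks a monotone likelihood
    if np.abs(beta).max() > 20.0 or se.max() > 10.0:
        raise CoxConvergenceError(
            "monotone likelihood / complete separation: no finite MLE"
        )
    return beta, se, ll


def _fit_table(beta: np.ndarray, se: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    z = beta / se
    table = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "wald_z": z,
            "p": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        },
        index=pd.Index(names, name="covariate"),
    )
    return table


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit by maximum partial likelihood.

    Rows with missing values in any used column are dropped (listwise
    deletion).  Returns one row per covariate with columns ``beta``, ``hr``,
    ``ci_low``, ``ci_high`` (Wald 95%), ``wald_z`` and ``p``.
    """
    covariates = list(covariates)
    cols = [time_col, event_col] + covariates
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    if len(complete) < len(sub):
        logger.info(
            "cox_fit: %d of %d rows dropped for missing data",
            len(sub) - len(complete), len(sub),
        )
    time = complete[time_col].to_numpy(dtype=float)
    event = complete[event_col].to_numpy(dtype=float)
    if not (event == event.astype(int)).all() or not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if event.sum() < 1:
        raise CoxError("no events among complete cases")
    X = complete[covariates].to_numpy(dtype=float)
    const = [c for c, v in zip(covariates, X.T) if np.ptp(v) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    beta, se, ll = _newton_cox(X, time, event)
    table = _fit_table(beta, se, covariates)
    table.attrs["loglik"] = ll
    table.attrs["n"] = len(complete)
    table.attrs["n_events"] = int(event.sum())
    return table


def univariate_wald_z(x, time, event) -> float:
    """Wald Z of a single-covariate Cox fit (fast path for resampling)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise CoxError("constant covariate")
    beta, se, _ = _newton_cox(
        x[:, None], np.asarray(time, float), np.asarray(event, float)
    )
    return float(beta[0] / se[0])


def stratified_cox(
    data: pd.DataFrame,
    covariates: Sequence[str],
    stratum_col: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> dict[object, pd.DataFrame]:
    """Independent Cox fits within each level of ``stratum_col``.

    Strata without events (or with a failed fit) are skipped with a warning
    and absent from the returned mapping.
    """
    if stratum_col not in data.columns:
        raise ValueError(f"missing stratum column {stratum_col!r}")
    fits: dict[object, pd.DataFrame] = {}
    for label, sub in data.groupby(stratum_col, sort=True):
        if len(sub) == 0:
            continue
        try:
            fits[label] = cox_fit(sub, covariates, time_col, event_col)
        except (CoxError, ValueError) as exc:
            logger.warning("stratum %r skipped: %s", label, exc)
    if not fits:
        raise CoxError("no stratum could be fit")
    return fits


def km_estimate(
    time, event, group=None
) -> Mapping[object, pd.Series]:
    """Kaplan-Meier product-limit survival curves, one per group label.

    Returns ``{label: S(t)}`` with each curve a Series indexed by time,
    starting at S(0) = 1.  With ``group=None`` a single curve keyed ``'all'``
    is returned.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValueError("empty survival data")
    labels = np.asarray(["all"] * len(time)) if group is None else np.asarray(group)
    curves: dict[object, pd.Series] = {}
    for label in pd.unique(labels):
        mask = labels == label
        if not mask.any():
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        s = kmf.survival_function_["KM_estimate"]
        s.index.name = "time"
        curves[label] = s
    return curves


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a = group == labels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)
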