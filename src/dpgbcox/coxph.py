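"""Clustered Cox partial likelihood, Newton solver, and Breslow post-processing.

Within cluster k, subject i with an observed event contributes the factor

    l_ik(beta) = exp(x~_i' beta) / sum_{j in R_k(T_i)} exp(x~_j' beta),

where x~ = (a, z, v) and R_k(t) = {j : s_j = k, T_j >= t} is the cluster-wise
risk set (a subject is at risk at its own event time). Censored subjects
contribute 1. The product over clusters and subjects is free of the baseline
hazards, so it identifies beta without modelling them. Tied event times are
handled Breslow-style: tied events share one risk-set denominator.

All heavy computation shifts linear predictors by the per-cluster maximum
before exponentiating (log-sum-exp), so values are finite for linear
predictors up to about +-700.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import SurvivalDataset

__all__ = [
    "RiskSetIndex",
    "CoxFit",
    "CumulativeHazard",
    "build_risk_sets",
    "partial_factor_log",
    "clustered_partial_loglik",
    "fit_cox_mle",
    "breslow_cumhaz",
]


@dataclass
class RiskSetIndex:
    """Cluster-wise risk-set bookkeeping.

    For each cluster label k: the member indices sorted by increasing time,
    their sorted times, and the original assignments.
    """

    assignments: np.ndarray
    members: list[np.ndarray] = field(init=False)
    sorted_times: list[np.ndarray] = field(init=False)

    def __init__(self, ds: SurvivalDataset, assignments: np.ndarray):
        self.assignments = np.asarray(assignments, dtype=np.int64)
        if self.assignments.shape[0] != ds.n:
            raise ValueError("assignments length must equal dataset size")
        self._time = ds.time
        K = int(self.assignments.max()) + 1 if ds.n else 0
        self.members = []
        self.sorted_times = []
        for k in range(K):
            idx = np.flatnonzero(self.assignments == k)
            order = np.argsort(ds.time[idx], kind="stable")
            self.members.append(idx[order])
            self.sorted_times.append(ds.time[idx][order])

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def at_risk(self, i: int) -> np.ndarray:
        """Indices of cluster members still at risk at subject i's time (T_j >= T_i)."""
        k = self.assignments[i]
        pos = np.searchsorted(self.sorted_times[k], self._time[i], side="left")
        return self.members[k][pos:]


def build_risk_sets(ds: SurvivalDataset, assignments) -> RiskSetIndex:
    return RiskSetIndex(ds, np.asarray(assignments, dtype=np.int64))


def partial_factor_log(i: int, beta, ds: SurvivalDataset, rsi: RiskSetIndex) -> float:
    """Log of subject i's own partial-likelihood factor; exactly 0 when censored."""
    if ds.event[i] == 0:
        return 0.0
    beta = np.asarray(beta, dtype=float)
    risk = rsi.at_risk(i)
    assert i in risk, "subject must belong to its own risk set"
    lp = ds.covariates()[risk] @ beta
    m = lp.max()
    denom = m + np.log(np.sum(np.exp(lp - m)))
    lp_i = float(ds.covariates()[i] @ beta)
    return lp_i - float(denom)


def _cluster_suffix_stats(time, event, lp, X=None, need_hess=False):
    """Suffix (T_j >= t) sums of exp(lp - max), optionally weighted by X and XX'.

    Returns per-event-subject contributions to the log-likelihood, gradient and
    Hessian for one cluster, given arrays already restricted to that cluster.
    """
    order = np.argsort(time, kind="stable")
    t_s, d_s, lp_s = time[order], event[order], lp[order]
    m = lp_s.max() if lp_s.size else 0.0
    w = np.exp(lp_s - m)
    s0 = np.cumsum(w[::-1])[::-1]
    # exact suffix log-sum-exp (stable even when the shifted weights underflow)
    log_s0 = np.logaddexp.accumulate(lp_s[::-1])[::-1]
    # tie handling: denominator index = first position with the same time
    pos = np.searchsorted(t_s, t_s, side="left")
    ev = d_s > 0
    ll = float(np.sum(lp_s[ev] - log_s0[pos[ev]]))
    if X is None:
        return ll, None, None
    X_s = X[order]
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
        xbar = s1[pos[ev]] / s0[pos[ev], None]
    # rare: a whole suffix underflowed the cluster-level shift; redo locally
    ev_idx = np.flatnonzero(ev)
    bad = np.flatnonzero(s0[pos[ev]] == 0.0)
    for b in bad:
        p = pos[ev_idx[b]]
        wloc = np.exp(lp_s[p:] - lp_s[p:].max())
        xbar[b] = wloc @ X_s[p:] / wloc.sum()
    grad = np.sum(X_s[ev] - xbar, axis=0)
    hess = None
    if need_hess:
        with np.errstate(invalid="ignore", divide="ignore"):
            outer = w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :])
            s2 = np.cumsum(outer[::-1], axis=0)[::-1]
            v = s2[pos[ev]] / s0[pos[ev], None, None] \
                - xbar[:, :, None] * xbar[:, None, :]
        for b in bad:
            p = pos[ev_idx[b]]
            wloc = np.exp(lp_s[p:] - lp_s[p:].max())
            wloc /= wloc.sum()
            m2 = (wloc[:, None, None] * X_s[p:, :, None] * X_s[p:, None, :]).sum(0)
            v[b] = m2 - np.outer(xbar[b], xbar[b])
        hess = -np.sum(v, axis=0)
    return ll, grad, hess


def clustered_partial_loglik(beta, ds: SurvivalDataset, assignments,
                             X: np.ndarray | None = None,
                             need_hess: bool = False):
    """Value and analytic gradient (optionally Hessian) of the clustered partial log-likelihood.

    Parameters
    ----------
    X : optional design matrix overriding ``ds.covariates()``.

    Returns ``(value, gradient)`` or ``(value, gradient, hessian)`` when
    ``need_hess`` is true.
    """
    beta = np.asarray(beta, dtype=float)
    if X is None:
        X = ds.covariates()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates")
    assignments = np.asarray(assignments, dtype=np.int64)
    lp = X @ beta
    p = X.shape[1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for k in range(int(assignments.max()) + 1):
        idx = np.flatnonzero(assignments == k)
        if idx.size == 0:
            continue
        llk, gk, hk = _cluster_suffix_stats(
            ds.time[idx], ds.event[idx], lp[idx], X[idx], need_hess)
        ll += llk
        grad += gk
        if need_hess:
            hess += hk
    if need_hess:
        return ll, grad, hess
    return ll, grad


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit with Wald inference."""

    estimate: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    ci_level: float
    conf_int: np.ndarray  # shape (p, 2)
    converged: bool
    n_events: int
    n_iter: int
    loglik: float
    names: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        names = self.names or [f"x{j}" for j in range(self.estimate.size)]
        return pd.DataFrame({
            "coef": self.estimate, "se": self.se,
            "ci_low": self.conf_int[:, 0], "ci_high": self.conf_int[:, 1],
            "hr": np.exp(self.estimate),
        }, index=names)


def fit_cox_mle(
    ds: SurvivalDataset,
    covariates: np.ndarray | None = None,
    names: list[str] | None = None,
    strata=None,
    ci_level: float = 0.95,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    rel_tol: float = 1e-10,
) -> CoxFit:
    """Newton–Raphson maximum of the (optionally stratified) Cox partial likelihood.

    ``covariates`` defaults to (a, z, v); ``strata`` defaults to a single
    stratum. Covariance is the inverse observed information at the optimum;
    columns that are constant (no information) are pinned at 0 with infinite
    variance and the fit flagged. Step-halving guards each Newton step.
    """
    X = ds.covariates() if covariates is None else np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    s = (np.zeros(ds.n, dtype=np.int64) if strata is None
         else _encode_strata(strata))
    if ds.n_events == 0:
        raise ValueError("no events in dataset")
    for k in np.unique(s):
        if ds.event[s == k].sum() == 0:
            raise ValueError(f"stratum {k} has zero events")
    p = X.shape[1]
    active = np.array([np.ptp(X[:, j]) > 0 for j in range(p)])
    Xa = X[:, active]
    beta_a = np.zeros(int(active.sum()))
    ll, g, H = clustered_partial_loglik(beta_a, ds, s, X=Xa, need_hess=True)
    converged = beta_a.size == 0
    it = 0
    degenerate = not active.all()
    for it in range(1, max_iter + 1) if beta_a.size else []:
        if np.max(np.abs(g)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            degenerate = True
            break
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta_a + scale * step
            ll_new, g_new, H_new = clustered_partial_loglik(
                cand, ds, s, X=Xa, need_hess=True)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta_a, ll, g, H = cand, ll_new, g_new, H_new
        if rel_change < rel_tol and np.max(np.abs(g)) < 1e-4:
            converged = True
            break
    if beta_a.size:
        try:
            cov_a = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_a = np.full((beta_a.size, beta_a.size), np.nan)
            converged = False
    else:
        cov_a = np.zeros((0, 0))
    beta = np.zeros(p)
    beta[active] = beta_a
    cov = np.full((p, p), np.inf)
    cov[np.ix_(active, active)] = cov_a
    se = np.sqrt(np.abs(np.diag(cov)))
    zq = norm.ppf(0.5 + ci_level / 2.0)
    ci = np.column_stack([beta - zq * se, beta + zq * se])
    return CoxFit(
        estimate=beta, covariance=cov, se=se, ci_level=ci_level, conf_int=ci,
        converged=converged,
        n_events=ds.n_events, n_iter=it, loglik=ll, names=names,
    )


def _encode_strata(strata) -> np.ndarray:
    _, inv = np.unique(np.asarray(strata), return_inverse=True)
    return inv.astype(np.int64)


@dataclass
class CumulativeHazard:
    """Breslow step-function cumulative baseline hazard for one cluster."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) < 0):
            raise ValueError("cumulative hazard must be non-decreasing")

    def at(self, t: float) -> float:
        """Value of the step function at time t (0 before the first event)."""
        pos = np.searchsorted(self.times, t, side="right")
        return 0.0 if pos == 0 else float(self.values[pos - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "cumhaz": self.values})


def breslow_cumhaz(beta, ds: SurvivalDataset, assignments, k: int) -> CumulativeHazard:
    """Breslow cumulative baseline hazard of cluster k at coefficient ``beta``.

    Jump at each distinct event time t: (# events at t) / sum_{R_k(t)} exp(lp).
    Provided as descriptive post-processing of posterior or MLE coefficients.
    """
    beta = np.asarray(beta, dtype=float)
    assignments = np.asarray(assignments, dtype=np.int64)
    idx = np.flatnonzero(assignments == k)
    t_k, d_k = ds.time[idx], ds.event[idx]
    if d_k.sum() == 0:
        raise ValueError(f"cluster {k} has no events")
    lp = ds.covariates()[idx] @ beta
    order = np.argsort(t_k, kind="stable")
    t_s, d_s, lp_s = t_k[order], d_k[order], lp[order]
    w = np.exp(lp_s)
    s0 = np.cumsum(w[::-1])[::-1]
    event_times = np.unique(t_s[d_s > 0])
    jumps = np.empty(event_times.size)
    for j, t in enumerate(event_times):
        pos = np.searchsorted(t_s, t, side="left")
        n_events = int(np.sum(d_s[t_s == t]))
        jumps[j] = n_events / s0[pos]
    return CumulativeHazard(times=event_times, values=np.cumsum(jumps))
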