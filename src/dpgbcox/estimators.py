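"""Hazard-ratio estimators as scikit-learn-style classes.

All estimators consume a :class:`~dpgbcox.data.SurvivalDataset` in ``fit``
and expose the fitted log hazard ratio of the exposure as ``coef_``, its
standard error as ``se_``, and a 95% (configurable) interval as
``conf_int_``. Module-level functions (``naive_cox`` etc.) are thin wrappers
returning an :class:`EstimateRecord`.

Frequentist comparators:

* :class:`NaiveCox` — unstratified Cox fit of (a, z, v); ignores the latent
  cluster structure.
* :class:`InfeasibleCox` — Cox fit stratified by the *true* cluster label
  (cluster-specific baseline hazards); the benchmark that uses unmeasured
  confounder information.
* :class:`TwoStageLeastSquares` — stage 1: OLS of A on (1, Z); stage 2: Cox
  fit with the fitted values A-hat replacing A.
* :class:`TwoStageResidualInclusion` — stage 1 as above; stage 2: Cox fit of
  (a, z, v, r-hat) with r-hat the first-stage residuals.

Two-stage standard errors are the naive Cox SEs from stage 2 (no
generated-regressor correction), matching how replication-based metrics are
computed.

The proposed method is :class:`DPGeneralBayesCox`, wrapping the
Dirichlet-process general-Bayes Gibbs sampler; its point estimate is the
posterior mean and its interval the equal-tailed credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from sklearn.base import BaseEstimator

from .coxph import CoxFit, fit_cox_mle
from .data import SurvivalDataset
from .sampler import PosteriorDraws, SamplerConfig, run_sampler, summarize_posterior

__all__ = [
    "EstimateRecord", "NaiveCox", "InfeasibleCox", "TwoStageLeastSquares",
    "TwoStageResidualInclusion", "DPGeneralBayesCox",
    "naive_cox", "infeasible_cox", "two_stage_least_squares",
    "two_stage_residual_inclusion",
]


@dataclass
class EstimateRecord:
    """One method's log-HR estimate with Wald/credible interval."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool = True
    first_stage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be non-negative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must contain the estimate")

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.estimate))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if f.name != "first_stage"}


class _BaseCoxEstimator(BaseEstimator):
    """Shared fit plumbing: runs a Cox MLE and stores sklearn-style attributes."""

    method_name = "base"

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def _store(self, fit: CoxFit, target: int = 0,
               first_stage: dict | None = None) -> "EstimateRecord":
        self.fit_ = fit
        self.coef_ = float(fit.estimate[target])
        self.se_ = float(fit.se[target])
        self.conf_int_ = (float(fit.conf_int[target, 0]),
                          float(fit.conf_int[target, 1]))
        self.hazard_ratio_ = float(np.exp(self.coef_))
        self.record_ = EstimateRecord(
            method=self.method_name, estimate=self.coef_, se=self.se_,
            ci_low=self.conf_int_[0], ci_high=self.conf_int_[1],
            converged=fit.converged, first_stage=first_stage or {})
        return self.record_


class NaiveCox(_BaseCoxEstimator):
    """Unstratified Cox fit of (exposure, Z, V); no confounder adjustment."""

    method_name = "naive"

    def fit(self, ds: SurvivalDataset, y=None) -> "NaiveCox":
        self._store(fit_cox_mle(ds, ci_level=self.ci_level))
        return self


class InfeasibleCox(_BaseCoxEstimator):
    """Cox fit of (exposure, Z, V) stratified by the true cluster label."""

    method_name = "infeasible"

    def fit(self, ds: SurvivalDataset, labels=None) -> "InfeasibleCox":
        if labels is None:
            raise ValueError("InfeasibleCox requires the true cluster labels")
        labels = np.asarray(labels)
        if labels.shape[0] != ds.n:
            raise ValueError("labels length must equal dataset size")
        self._store(fit_cox_mle(ds, strata=labels, ci_level=self.ci_level))
        return self


def _first_stage_ols(ds: SurvivalDataset) -> tuple[np.ndarray, np.ndarray, dict]:
    """OLS of A on (1, Z); returns fitted values, residuals, diagnostics."""
    if ds.z.shape[1] == 0:
        raise ValueError("two-stage methods require dim Z >= 1")
    if np.any(np.ptp(ds.z, axis=0) == 0):
        raise ValueError("no first-stage signal: a Z column is constant")
    design = np.column_stack([np.ones(ds.n), ds.z])
    coef, *_ = np.linalg.lstsq(design, ds.exposure, rcond=None)
    fitted = design @ coef
    resid = ds.exposure - fitted
    tss = float(np.sum((ds.exposure - ds.exposure.mean()) ** 2))
    rss = float(np.sum(resid ** 2))
    diag = {"coef": coef.tolist(), "r2": 1.0 - rss / tss if tss > 0 else 0.0}
    return fitted, resid, diag


class TwoStageLeastSquares(_BaseCoxEstimator):
    """2SLS for the Cox model: predicted exposure replaces the exposure in stage 2."""

    method_name = "2sls"

    def fit(self, ds: SurvivalDataset, y=None) -> "TwoStageLeastSquares":
        fitted, _, diag = _first_stage_ols(ds)
        # Z is the instrument and is excluded from stage 2: A-hat is an exact
        # linear function of (1, Z), so including Z again would make the
        # design rank-deficient and beta_a unidentified.
        X = np.column_stack([fitted, ds.v])
        self._store(fit_cox_mle(ds, covariates=X, ci_level=self.ci_level),
                    first_stage=diag)
        return self


class TwoStageResidualInclusion(_BaseCoxEstimator):
    """2SRI: exposure plus first-stage residuals as stage-2 regressors."""

    method_name = "2sri"

    def fit(self, ds: SurvivalDataset, y=None) -> "TwoStageResidualInclusion":
        _, resid, diag = _first_stage_ols(ds)
        if np.allclose(resid, 0.0):
            raise ValueError("first-stage residuals are identically zero "
                             "(saturated first stage; collinear with exposure)")
        # Z excluded from stage 2 for the same identifiability reason as in
        # 2SLS: a - z'alpha_z - r-hat is constant by the first-stage identity.
        X = np.column_stack([ds.exposure, ds.v, resid])
        self._store(fit_cox_mle(ds, covariates=X, ci_level=self.ci_level),
                    first_stage=diag)
        return self


class DPGeneralBayesCox(BaseEstimator):
    """Dirichlet-process general-Bayes Cox estimator (the proposed method).

    Runs the Gibbs sampler of :func:`dpgbcox.sampler.run_sampler` on fit.
    The point estimate is the posterior mean of beta_a; the interval is the
    equal-tailed credible interval at ``ci_level``.

    Fitted attributes
    -----------------
    draws_ : PosteriorDraws
    summary_ : dict of posterior summaries
    coef_, se_, conf_int_, hazard_ratio_ : exposure log-HR summaries
    clustering_ : representative subject grouping
    """

    method_name = "proposed"

    def __init__(self, n_iter: int = 4000, n_burn: int = 2000, thin: int = 1,
                 seed: int = 0, learning_rate: float = 1.0,
                 cluster_specific: tuple = ("alpha0", "alpha_v", "sigma2"),
                 assignment_rule: str = "exposure_only", m_aux: int = 3,
                 b_shrink: float = 1.0, n_mh_steps: int = 1,
                 proposal_scale: float = 0.1, ci_level: float = 0.95,
                 n_groups="modal_k", init_clusters: int = 8):
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed
        self.learning_rate = learning_rate
        self.cluster_specific = cluster_specific
        self.assignment_rule = assignment_rule
        self.m_aux = m_aux
        self.b_shrink = b_shrink
        self.n_mh_steps = n_mh_steps
        self.proposal_scale = proposal_scale
        self.ci_level = ci_level
        self.n_groups = n_groups
        self.init_clusters = init_clusters

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iter=self.n_iter, n_burn=self.n_burn, thin=self.thin,
            seed=self.seed, learning_rate=self.learning_rate,
            cluster_specific=tuple(self.cluster_specific),
            assignment_rule=self.assignment_rule, m_aux=self.m_aux,
            b_shrink=self.b_shrink, n_mh_steps=self.n_mh_steps,
            proposal_scale=self.proposal_scale, init_clusters=self.init_clusters)

    def fit(self, ds: SurvivalDataset, y=None) -> "DPGeneralBayesCox":
        draws: PosteriorDraws = run_sampler(ds, self._config())
        summary = summarize_posterior(draws, self.ci_level, self.n_groups)
        self.draws_ = draws
        self.summary_ = summary
        self.coef_ = summary["beta_a"]["mean"]
        self.se_ = float(np.std(draws.beta_a, ddof=1))
        self.conf_int_ = (summary["beta_a"]["ci_low"], summary["beta_a"]["ci_high"])
        self.hazard_ratio_ = summary["hazard_ratio"]["mean"]
        self.clustering_ = np.asarray(summary["clustering"])
        self.record_ = EstimateRecord(
            method=self.method_name, estimate=self.coef_, se=self.se_,
            ci_low=self.conf_int_[0], ci_high=self.conf_int_[1])
        return self


def naive_cox(ds: SurvivalDataset) -> EstimateRecord:
    return NaiveCox().fit(ds).record_


def infeasible_cox(ds: SurvivalDataset, true_labels) -> EstimateRecord:
    return InfeasibleCox().fit(ds, true_labels).record_


def two_stage_least_squares(ds: SurvivalDataset) -> EstimateRecord:
    return TwoStageLeastSquares().fit(ds).record_


def two_stage_residual_inclusion(ds: SurvivalDataset) -> EstimateRecord:
    return TwoStageResidualInclusion().fit(ds).record_
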