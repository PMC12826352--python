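"""General-Bayes Gibbs sampler for the Dirichlet-process-clustered Cox model.

The joint general posterior combines (i) a CRP partition prior with Gamma
prior on the DP precision, (ii) the cluster-wise normal exposure likelihood,
(iii) the clustered Cox partial likelihood raised to a loss scale
(``learning_rate``, default 1) in place of an outcome likelihood, and (iv)
normal priors on beta_a, beta_v with an independent Laplace shrinkage prior
on beta_z:

    p(beta, alpha, Sigma, gamma, s | D) ∝ pi(beta, alpha_z, gamma)
        pi_G0(alpha_0, alpha_v, Sigma) P(s; gamma)
        prod_k prod_{i in C_k} l_ik(beta)^eta phi(A_i; mu_ik, sigma2_k).

One sweep updates, in order: alpha_z (conjugate normal) -> per-cluster
(alpha0_k, alpha_v_k) and sigma2_k (conjugate) -> cluster assignments
(CRP x own partial factor x exposure density, with Neal algorithm-8 auxiliary
components for the non-conjugate new-cluster move) -> gamma (Escobar-West)
-> beta (adaptive random-walk Metropolis on the general posterior).

Which of {alpha0, alpha_v, sigma2} are cluster-specific is configurable;
shared components are folded into the global regression (alpha0 shared
becomes an intercept column of Z, alpha_v shared appends V to Z, sigma2
shared pools all clusters' residuals in one inverse-gamma update).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import clustered_partial_loglik
from .crp import ConcentrationPrior, PartitionState, sample_gamma
from .data import SurvivalDataset
from .exposure import ClusterParams, ExposurePriors, update_alpha_z

__all__ = [
    "GlobalParams", "SamplerConfig", "PosteriorDraws",
    "update_assignments", "update_beta", "run_sampler",
    "summarize_posterior", "representative_clustering",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GlobalParams:
    """Cluster-shared parameters of the joint model."""

    beta_a: float
    beta_z: np.ndarray
    beta_v: np.ndarray
    alpha_z: np.ndarray
    gamma: float

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([[self.beta_a], self.beta_z, self.beta_v])


@dataclass
class SamplerConfig:
    """Tuning and prior settings for :func:`run_sampler`.

    ``cluster_specific`` lists which exposure-model components vary by
    cluster; the remainder are shared across clusters. ``learning_rate`` is
    the general-Bayes loss scale multiplying the partial log-likelihood.
    """

    n_iter: int = 4000
    n_burn: int = 2000
    thin: int = 1
    seed: int = 0
    cluster_specific: tuple[str, ...] = ("alpha0", "alpha_v", "sigma2")
    learning_rate: float = 1.0
    # beta priors
    m_beta_a: float = 0.0
    tau2_beta_a: float = 100.0
    m_beta_v: float = 0.0
    tau2_beta_v: float = 100.0
    b_shrink: float = 1.0  # Laplace scale on each beta_z coordinate
    # Metropolis proposal
    proposal_scale: float = 0.1
    adapt: bool = True
    n_mh_steps: int = 1
    # assignment update
    assignment_rule: str = "exposure_only"  # or "own_factor" / "exact_ratio"
    m_aux: int = 3
    exposure_priors: ExposurePriors = field(default_factory=ExposurePriors)
    concentration_prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)

    init_clusters: int = 8

    def __post_init__(self) -> None:
        if self.init_clusters < 1:
            raise ValueError("init_clusters must be >= 1")
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        unknown = set(self.cluster_specific) - {"alpha0", "alpha_v", "sigma2"}
        if unknown:
            raise ValueError(f"unknown cluster_specific entries {sorted(unknown)}")
        if self.assignment_rule not in ("exposure_only", "own_factor", "exact_ratio"):
            raise ValueError("assignment_rule must be 'exposure_only', "
                             "'own_factor' or 'exact_ratio'")


@dataclass
class PosteriorDraws:
    """Retained MCMC output (one row per retained sweep)."""

    beta_a: np.ndarray
    beta_z: np.ndarray
    beta_v: np.ndarray
    alpha_z: np.ndarray
    gamma: np.ndarray
    n_clusters: np.ndarray
    assignments: np.ndarray       # (n_ret, n) int16
    subject_alpha0: np.ndarray    # (n_ret, n): alpha0 of each subject's cluster
    log_post: np.ndarray
    accept_rate: float = float("nan")

    @property
    def n_retained(self) -> int:
        return int(self.beta_a.shape[0])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (iteration, parameter, value) trace of scalar parameters."""
        rows = {"beta_a": self.beta_a, "gamma": self.gamma,
                "n_clusters": self.n_clusters, "log_post": self.log_post}
        for j in range(self.beta_z.shape[1]):
            rows[f"beta_z{j + 1}"] = self.beta_z[:, j]
        for j in range(self.beta_v.shape[1]):
            rows[f"beta_v{j + 1}"] = self.beta_v[:, j]
        for j in range(self.alpha_z.shape[1]):
            rows[f"alpha_z{j + 1}"] = self.alpha_z[:, j]
        frames = [pd.DataFrame({"iteration": np.arange(len(v)),
                                "parameter": name, "value": v})
                  for name, v in rows.items()]
        return pd.concat(frames, ignore_index=True)


class _EffectiveModel:
    """Re-expresses shared/cluster-specific flags as an equivalent model.

    Builds the exposure-side dataset with effective Z (original Z, plus an
    intercept column when alpha0 is shared, plus V when alpha_v is shared)
    and effective V (original V only when alpha_v is cluster-specific), and
    the matching column-wise priors for the effective alpha_z block.
    """

    def __init__(self, ds: SurvivalDataset, cfg: SamplerConfig):
        self.ds = ds
        self.cluster_alpha0 = "alpha0" in cfg.cluster_specific
        self.cluster_alpha_v = "alpha_v" in cfg.cluster_specific and ds.v.shape[1] > 0
        self.shared_sigma2 = "sigma2" not in cfg.cluster_specific
        pri = cfg.exposure_priors
        z_blocks = [ds.z]
        m_z, v_z = pri.alpha_z_prior(ds.z.shape[1])
        means = [m_z]
        vars_ = [v_z]
        if not self.cluster_alpha0:
            z_blocks.append(np.ones((ds.n, 1)))
            means.append([pri.m_alpha0])
            vars_.append([pri.tau2_alpha0])
        if not self.cluster_alpha_v and ds.v.shape[1] > 0:
            z_blocks.append(ds.v)
            m_v, v_v = pri.alpha_v_prior(ds.v.shape[1])
            means.append(m_v)
            vars_.append(v_v)
        z_eff = np.column_stack(z_blocks) if ds.n else np.empty((0, 0))
        v_eff = ds.v if self.cluster_alpha_v else None
        self.exposure_ds = SurvivalDataset(
            time=ds.time, event=ds.event, exposure=ds.exposure,
            z=z_eff, v=v_eff)
        self.priors = ExposurePriors(
            m_alpha0=pri.m_alpha0, tau2_alpha0=pri.tau2_alpha0,
            m_alpha_v=pri.alpha_v_prior(ds.v.shape[1])[0] if self.cluster_alpha_v else 0.0,
            var_alpha_v=pri.alpha_v_prior(ds.v.shape[1])[1] if self.cluster_alpha_v else 100.0,
            m_alpha_z=np.concatenate(means) if z_eff.shape[1] else 0.0,
            var_alpha_z=np.concatenate(vars_) if z_eff.shape[1] else 100.0,
            a_sigma=pri.a_sigma, b_sigma=pri.b_sigma)
        self.p_v_eff = self.exposure_ds.v.shape[1]

    def draw_new_cluster(self, rng: np.random.Generator,
                         current_sigma2: float) -> tuple[float, np.ndarray, float]:
        """G0 draw restricted to the cluster-specific components."""
        pri = self.priors
        a0 = (rng.normal(pri.m_alpha0, np.sqrt(pri.tau2_alpha0))
              if self.cluster_alpha0 else 0.0)
        if self.p_v_eff:
            m_v, v_v = pri.alpha_v_prior(self.p_v_eff)
            av = rng.normal(m_v, np.sqrt(v_v))
        else:
            av = np.zeros(0)
        if self.shared_sigma2:
            s2 = current_sigma2
        else:
            s2 = 1.0 / rng.gamma(pri.a_sigma, 1.0 / pri.b_sigma)
        return float(a0), np.atleast_1d(av), float(s2)


class _ClusterRiskIndex:
    """Per-cluster sorted times, suffix sums of shifted hazards exp(lp - M),
    and per-event denominators (for the exact-ratio assignment rule)."""

    def __init__(self, ds: SurvivalDataset, assignments: np.ndarray, lp: np.ndarray):
        self.time = ds.time
        self.event = ds.event
        self.shift = float(lp.max()) if lp.size else 0.0
        self.w = np.exp(lp - self.shift)
        self.times: list[np.ndarray] = []
        self.suffix: list[np.ndarray] = []
        self.ev_times: list[np.ndarray] = []
        self.ev_denom: list[np.ndarray] = []
        for k in range(int(assignments.max()) + 1):
            self._build(k, assignments)

    def _build(self, k: int, assignments: np.ndarray) -> None:
        idx = np.flatnonzero(assignments == k)
        order = np.argsort(self.time[idx], kind="stable")
        t = self.time[idx][order]
        w = self.w[idx][order]
        d = self.event[idx][order]
        suf = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        ev = d > 0
        ev_t = t[ev]
        ev_denom = suf[np.searchsorted(t, ev_t, side="left")]
        if k < len(self.times):
            self.times[k], self.suffix[k] = t, suf
            self.ev_times[k], self.ev_denom[k] = ev_t, ev_denom
        else:
            self.times.append(t)
            self.suffix.append(suf)
            self.ev_times.append(ev_t)
            self.ev_denom.append(ev_denom)

    def rebuild(self, k: int, assignments: np.ndarray) -> None:
        self._build(k, assignments)

    def remove_cluster(self, k: int) -> None:
        del self.times[k]
        del self.suffix[k]
        del self.ev_times[k]
        del self.ev_denom[k]

    def denom(self, k: int, t: float) -> float:
        """Suffix sum of cluster-k shifted hazards over members with T_j >= t."""
        pos = np.searchsorted(self.times[k], t, side="left")
        return float(self.suffix[k][pos])

    def join_penalty(self, k: int, t: float, w_i: float) -> float:
        """Increase of cluster-k event denominators when a subject with time t
        and shifted hazard w_i joins: sum of log(1 + w_i / D) over events <= t."""
        pos = np.searchsorted(self.ev_times[k], t, side="right")
        if pos == 0:
            return 0.0
        return float(np.log1p(w_i / self.ev_denom[k][:pos]).sum())

    def leave_gain(self, k: int, t: float, w_i: float, exclude_own: bool) -> float:
        """Decrease (as a positive number) of cluster-k event denominators when
        a member with time t and shifted hazard w_i leaves. ``exclude_own``
        drops one event term at time t (the leaving member's own event; tied
        events share the same denominator, so excluding any one is equivalent)."""
        pos = np.searchsorted(self.ev_times[k], t, side="right")
        if pos == 0:
            return 0.0
        with np.errstate(divide="ignore"):
            terms = np.log1p(-w_i / self.ev_denom[k][:pos])
        if exclude_own:
            j = np.searchsorted(self.ev_times[k], t, side="left")
            if j < pos:
                terms[j] = 0.0
        return float(-terms.sum())


def _log_phi_all_clusters(a_i: float, mu_shared_i: float, v_i: np.ndarray,
                          cp: ClusterParams) -> np.ndarray:
    mu = cp.alpha0 + mu_shared_i + cp.alpha_v @ v_i
    return -0.5 * (_LOG_2PI + np.log(cp.sigma2)) - 0.5 * (a_i - mu) ** 2 / cp.sigma2


def update_assignments(
    ds: SurvivalDataset,
    part: PartitionState,
    cp: ClusterParams,
    gp: GlobalParams,
    config: SamplerConfig,
    rng: np.random.Generator,
    eff: "_EffectiveModel | None" = None,
) -> tuple[PartitionState, ClusterParams]:
    """One full sweep of per-subject cluster reassignments.

    Under the default cut rule (``assignment_rule='exposure_only'``) the
    conditional for s_i = k is the held-out CRP weight times the exposure
    density under cluster k's parameters; the new-cluster option is scored
    by Neal algorithm-8 auxiliary components (m fresh G0 draws; a singleton
    subject's current parameters occupy the first slot). The partition is
    thus informed by the exposure model, and the Cox factor informs beta
    given the partition.

    ``assignment_rule='own_factor'`` additionally multiplies in subject i's
    own partial-likelihood factor l_ik (raised to the loss scale), the
    conditional of the uncut joint posterior read factor-by-factor;
    ``'exact_ratio'`` uses the exact change in the full clustered partial
    log-likelihood instead of the single factor. Both uncut rules reward
    small risk sets (a new cluster's factor is exactly 1), which drives the
    partition toward fragmentation; they are provided for study, not as
    defaults.
    """
    if eff is None:
        eff = _EffectiveModel(ds, config)
    exp_ds = eff.exposure_ds
    s = part.assignments.copy()
    sizes = part.sizes.copy().astype(np.int64)
    cp = cp.copy()
    lr = config.learning_rate
    exact = config.assignment_rule == "exact_ratio"
    use_cox_factor = config.assignment_rule != "exposure_only"
    lp = ds.covariates() @ gp.beta
    idxr = _ClusterRiskIndex(ds, s, lp)
    lps = lp - idxr.shift
    w = idxr.w
    mu_shared = exp_ds.z @ gp.alpha_z if exp_ds.z.shape[1] else np.zeros(ds.n)
    v = exp_ds.v
    p_v = v.shape[1]
    gamma = gp.gamma
    m_aux = max(1, config.m_aux)
    log_gamma_m = np.log(gamma / m_aux)
    pri = eff.priors
    # batch G0 draws for the auxiliary components (reproducible given the rng)
    if eff.cluster_alpha0:
        a0_aux = rng.normal(pri.m_alpha0, np.sqrt(pri.tau2_alpha0), (ds.n, m_aux))
    else:
        a0_aux = np.zeros((ds.n, m_aux))
    if p_v:
        m_v, v_v = pri.alpha_v_prior(p_v)
        av_aux = rng.normal(m_v, np.sqrt(v_v), (ds.n, m_aux, p_v))
    else:
        av_aux = np.zeros((ds.n, m_aux, 0))
    if eff.shared_sigma2:
        s2_aux = np.full((ds.n, m_aux), float(cp.sigma2[0]))
    else:
        s2_aux = 1.0 / rng.gamma(pri.a_sigma, 1.0 / pri.b_sigma, (ds.n, m_aux))
    u_choice = rng.random(ds.n)

    time_arr, event_arr, expo = ds.time, ds.event, ds.exposure
    for i in range(ds.n):
        cur = s[i]
        singleton = sizes[cur] == 1
        n_minus = sizes.astype(float)
        n_minus[cur] -= 1.0
        K = sizes.shape[0]
        logphi = _log_phi_all_clusters(expo[i], mu_shared[i], v[i], cp)
        with np.errstate(divide="ignore"):
            logw = np.log(n_minus) + logphi  # -inf for the emptied own cluster
        t_i = time_arr[i]
        w_i = w[i]
        d_i = event_arr[i]
        if lr > 0 and use_cox_factor:
            if exact:
                # change in total clustered partial log-lik from placing i in k,
                # relative to i removed; computed incrementally via suffix sums
                own_cur = (lps[i] - np.log(idxr.denom(cur, t_i))) if d_i else 0.0
                base_cur = own_cur - idxr.leave_gain(cur, t_i, w_i, bool(d_i))
                for k in range(K):
                    if n_minus[k] <= 0:
                        continue
                    if k == cur:
                        logw[k] += lr * base_cur
                    else:
                        own = (lps[i] - np.log(idxr.denom(k, t_i) + w_i)) if d_i else 0.0
                        logw[k] += lr * (own - idxr.join_penalty(k, t_i, w_i))
            elif d_i:
                for k in range(K):
                    if n_minus[k] <= 0:
                        continue
                    d = idxr.denom(k, t_i)
                    if k != cur:
                        d += w_i
                    logw[k] += lr * (lps[i] - np.log(d))
        # auxiliary new-cluster components (Neal algorithm 8)
        a0s, avs, s2s = a0_aux[i].copy(), av_aux[i].copy(), s2_aux[i].copy()
        if singleton:
            a0s[0], avs[0], s2s[0] = cp.alpha0[cur], cp.alpha_v[cur], cp.sigma2[cur]
        mu = a0s + mu_shared[i] + (avs @ v[i] if p_v else 0.0)
        aux_logw = (log_gamma_m - 0.5 * (_LOG_2PI + np.log(s2s))
                    - 0.5 * (expo[i] - mu) ** 2 / s2s)
        allw = np.concatenate([logw, aux_logw])
        p = np.exp(allw - allw.max())
        cum = np.cumsum(p)
        choice = int(np.searchsorted(cum, u_choice[i] * cum[-1], side="right"))
        choice = min(choice, allw.size - 1)

        if choice == cur:
            continue
        # move subject i
        sizes[cur] -= 1
        if choice >= K:  # open a new cluster with the chosen auxiliary params
            j = choice - K
            pars = (float(a0s[j]), avs[j], float(s2s[j]))
            if sizes[cur] == 0:
                # replace the emptied singleton cluster's parameters in place
                cp.alpha0[cur], cp.alpha_v[cur], cp.sigma2[cur] = pars
                sizes[cur] = 1
                continue
            s[i] = K
            sizes = np.append(sizes, 1)
            cp = ClusterParams(np.append(cp.alpha0, pars[0]),
                               np.vstack([cp.alpha_v, pars[1][None, :]]),
                               np.append(cp.sigma2, pars[2]))
            idxr.rebuild(cur, s)
            idxr.rebuild(K, s)
        else:
            s[i] = choice
            sizes[choice] += 1
            if sizes[cur] == 0:
                keep = np.ones(K, dtype=bool)
                keep[cur] = False
                s[s > cur] -= 1
                sizes = sizes[keep]
                cp = cp.subset(keep)
                idxr.remove_cluster(cur)
                idxr.rebuild(s[i], s)
            else:
                idxr.rebuild(cur, s)
                idxr.rebuild(choice, s)
    return PartitionState(s), cp


def _log_beta_prior(beta_a, beta_z, beta_v, config: SamplerConfig) -> float:
    lp = -0.5 * (beta_a - config.m_beta_a) ** 2 / config.tau2_beta_a
    lp += -0.5 * np.sum((beta_v - config.m_beta_v) ** 2) / config.tau2_beta_v
    lp += -np.sum(np.abs(beta_z)) / config.b_shrink  # Laplace shrinkage
    return float(lp)


class _AdaptiveRWM:
    """Random-walk Metropolis with burn-in-only covariance/scale adaptation."""

    def __init__(self, dim: int, config: SamplerConfig):
        self.dim = dim
        self.log_scale = np.log(max(config.proposal_scale, 1e-12))
        self.adapt = config.adapt and config.proposal_scale > 0
        self.chol = np.eye(dim)
        self.n_acc = 0
        self.n_prop = 0
        self._hist: list[np.ndarray] = []
        self.frozen = False

    def propose(self, x: np.ndarray, rng) -> np.ndarray:
        if not self.adapt and self.log_scale <= np.log(1e-12):
            return x.copy()  # degenerate zero-scale proposal: never moves
        return x + np.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def register(self, x: np.ndarray, accepted: bool, iteration: int) -> None:
        self.n_prop += 1
        self.n_acc += accepted
        if self.frozen or not self.adapt:
            return
        self._hist.append(x.copy())
        # Robbins-Monro scale tuning toward ~30% acceptance
        self.log_scale += ((1.0 if accepted else 0.0) - 0.3) / max(10, iteration) ** 0.6 * 3.0
        if len(self._hist) >= 200 and len(self._hist) % 100 == 0:
            h = np.asarray(self._hist[len(self._hist) // 2:])
            cov = np.cov(h.T) if self.dim > 1 else np.atleast_2d(np.var(h))
            cov = np.atleast_2d(cov) + 1e-9 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def freeze(self) -> None:
        self.frozen = True

    @property
    def accept_rate(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else float("nan")


def update_beta(
    ds: SurvivalDataset,
    part: PartitionState,
    gp: GlobalParams,
    config: SamplerConfig,
    rng: np.random.Generator,
    rwm: "_AdaptiveRWM | None" = None,
    iteration: int = 1,
    cached_loglik: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Adaptive random-walk Metropolis step(s) on beta = (beta_a, beta_z, beta_v).

    Target: learning_rate * clustered partial log-lik + log prior
    (normal on beta_a and beta_v, Laplace on beta_z).
    Returns the updated components and the partial log-lik at the new state.
    """
    p_z, p_v = ds.z.shape[1], ds.v.shape[1]
    beta = gp.beta.copy()
    if rwm is None:
        rwm = _AdaptiveRWM(beta.size, config)
    lr = config.learning_rate
    s = part.assignments

    def target(b):
        ll = (clustered_partial_loglik(b, ds, s)[0] if lr > 0 else 0.0)
        return lr * ll + _log_beta_prior(b[0], b[1:1 + p_z], b[1 + p_z:], config), ll

    cur_t, cur_ll = (target(beta) if cached_loglik is None
                     else (lr * cached_loglik
                           + _log_beta_prior(beta[0], beta[1:1 + p_z], beta[1 + p_z:], config),
                           cached_loglik))
    for _ in range(max(1, config.n_mh_steps)):
        prop = rwm.propose(beta, rng)
        prop_t, prop_ll = target(prop)
        accept = np.log(rng.uniform()) < prop_t - cur_t
        if accept:
            beta, cur_t, cur_ll = prop, prop_t, prop_ll
        rwm.register(beta, bool(accept), iteration)
    return float(beta[0]), beta[1:1 + p_z], beta[1 + p_z:], cur_ll


def run_sampler(ds: SurvivalDataset, config: SamplerConfig) -> PosteriorDraws:
    """Run the full Gibbs sampler and return retained draws.

    Initialization: the partition starts over-segmented (``init_clusters``
    quantile bins of the exposure; Dirichlet-process merges mix far faster
    than splits, so surplus bins are pruned during burn-in), gamma = 1,
    beta = 0, exposure coefficients at their prior means, sigma2 at the prior
    mean of its inverse-gamma (b/(a-1) when a > 1, else 1). Fully
    reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    eff = _EffectiveModel(ds, config)
    exp_ds = eff.exposure_ds
    p_z_eff = exp_ds.z.shape[1]
    p_v_eff = exp_ds.v.shape[1]
    pri = eff.priors

    any_cluster_specific = (eff.cluster_alpha0 or eff.p_v_eff > 0
                            or not eff.shared_sigma2)
    k0 = min(config.init_clusters, ds.n) if any_cluster_specific else 1
    if k0 > 1:
        edges = np.quantile(ds.exposure, np.linspace(0, 1, k0 + 1)[1:-1])
        init = np.searchsorted(edges, ds.exposure, side="right")
    else:
        init = np.zeros(ds.n, dtype=np.int64)
    part = PartitionState(init.astype(np.int64))
    m_z, _ = pri.alpha_z_prior(p_z_eff)
    alpha_z = m_z.copy()
    s2_init = pri.b_sigma / (pri.a_sigma - 1.0) if pri.a_sigma > 1 else 1.0
    m_v, _ = pri.alpha_v_prior(p_v_eff)
    K0 = part.n_clusters
    cp = ClusterParams(
        alpha0=np.full(K0, pri.m_alpha0 if eff.cluster_alpha0 else 0.0),
        alpha_v=np.tile(m_v, (K0, 1)) if p_v_eff else np.zeros((K0, 0)),
        sigma2=np.full(K0, s2_init))
    gp = GlobalParams(beta_a=0.0, beta_z=np.zeros(ds.z.shape[1]),
                      beta_v=np.zeros(ds.v.shape[1]), alpha_z=alpha_z, gamma=1.0)
    rwm = _AdaptiveRWM(1 + ds.z.shape[1] + ds.v.shape[1], config)

    n_ret = (config.n_iter - config.n_burn) // config.thin
    out = PosteriorDraws(
        beta_a=np.empty(n_ret), beta_z=np.empty((n_ret, ds.z.shape[1])),
        beta_v=np.empty((n_ret, ds.v.shape[1])),
        alpha_z=np.empty((n_ret, p_z_eff)), gamma=np.empty(n_ret),
        n_clusters=np.empty(n_ret, dtype=np.int32),
        assignments=np.empty((n_ret, ds.n), dtype=np.int16),
        subject_alpha0=np.empty((n_ret, ds.n)), log_post=np.empty(n_ret))

    r = 0
    for it in range(1, config.n_iter + 1):
        if it == config.n_burn + 1:
            rwm.freeze()
        if p_z_eff:
            gp.alpha_z = update_alpha_z(exp_ds, part, cp, pri, rng)
        for k in range(part.n_clusters):
            a0_k, av_k = _cluster_block_draw(exp_ds, part, gp.alpha_z, pri, rng, k,
                                             float(cp.sigma2[k]), eff)
            cp.alpha0[k] = a0_k
            if p_v_eff:
                cp.alpha_v[k] = av_k
        _sigma2_sweep(exp_ds, part, gp.alpha_z, cp, pri, rng, eff)
        part, cp = update_assignments(ds, part, cp, gp, config, rng, eff)
        gp.gamma = sample_gamma(part.n_clusters, ds.n, gp.gamma,
                                config.concentration_prior, rng)
        gp.beta_a, gp.beta_z, gp.beta_v, ll = update_beta(
            ds, part, gp, config, rng, rwm, it)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite partial log-likelihood at iteration {it}")
        if it > config.n_burn and (it - config.n_burn - 1) % config.thin == 0:
            out.beta_a[r] = gp.beta_a
            out.beta_z[r] = gp.beta_z
            out.beta_v[r] = gp.beta_v
            out.alpha_z[r] = gp.alpha_z
            out.gamma[r] = gp.gamma
            out.n_clusters[r] = part.n_clusters
            out.assignments[r] = part.assignments
            out.subject_alpha0[r] = cp.alpha0[part.assignments]
            out.log_post[r] = _log_joint(ds, exp_ds, part, cp, gp, config, pri, ll)
            r += 1
    out.accept_rate = rwm.accept_rate
    return out


def _cluster_block_draw(exp_ds, part, alpha_z, pri, rng, k, sigma2_k, eff):
    """Conjugate draw of the cluster-specific coefficient block (may be empty)."""
    idx = np.flatnonzero(part.assignments == k)
    p_v = exp_ds.v.shape[1]
    has_icpt = eff.cluster_alpha0
    dim = int(has_icpt) + p_v
    if dim == 0:
        return 0.0, np.zeros(0)
    y = exp_ds.exposure[idx] - (exp_ds.z[idx] @ np.atleast_1d(alpha_z)
                                if exp_ds.z.shape[1] else 0.0)
    m0, v0 = [], []
    if has_icpt:
        m0.append(pri.m_alpha0)
        v0.append(pri.tau2_alpha0)
    if p_v:
        m_v, v_v = pri.alpha_v_prior(p_v)
        m0.extend(m_v)
        v0.extend(v_v)
    design = np.column_stack(
        ([np.ones((idx.size, 1))] if has_icpt else [])
        + ([exp_ds.v[idx]] if p_v else []))
    m0 = np.asarray(m0, float)
    v0 = np.asarray(v0, float)
    prec = np.diag(1.0 / v0) + design.T @ design / sigma2_k
    rhs = m0 / v0 + design.T @ y / sigma2_k
    cov = np.linalg.inv(prec)
    mean = cov @ rhs
    draw = mean + np.linalg.cholesky(cov) @ rng.standard_normal(dim)
    if has_icpt:
        return float(draw[0]), draw[1:]
    return 0.0, draw


def _sigma2_sweep(exp_ds, part, alpha_z, cp, pri, rng, eff) -> None:
    s = part.assignments
    mean = (cp.alpha0[s]
            + (exp_ds.z @ np.atleast_1d(alpha_z) if exp_ds.z.shape[1] else 0.0)
            + (np.einsum("ij,ij->i", exp_ds.v, cp.alpha_v[s]) if exp_ds.v.shape[1] else 0.0))
    resid2 = (exp_ds.exposure - mean) ** 2
    if eff.shared_sigma2:
        shape = pri.a_sigma + exp_ds.n / 2.0
        scale = pri.b_sigma + resid2.sum() / 2.0
        cp.sigma2[:] = 1.0 / rng.gamma(shape, 1.0 / scale)
    else:
        for k in range(part.n_clusters):
            rk = resid2[s == k]
            shape = pri.a_sigma + rk.size / 2.0
            scale = pri.b_sigma + rk.sum() / 2.0
            cp.sigma2[k] = 1.0 / rng.gamma(shape, 1.0 / scale)


def _log_joint(ds, exp_ds, part, cp, gp, config, pri, partial_ll) -> float:
    """Log of the joint general posterior kernel at the current state."""
    from .crp import log_eppf
    from scipy.stats import gamma as gamma_dist, invgamma, norm as norm_dist

    s = part.assignments
    mean = (cp.alpha0[s]
            + (exp_ds.z @ np.atleast_1d(gp.alpha_z) if exp_ds.z.shape[1] else 0.0)
            + (np.einsum("ij,ij->i", exp_ds.v, cp.alpha_v[s]) if exp_ds.v.shape[1] else 0.0))
    sig2 = cp.sigma2[s]
    ll_exp = float(np.sum(-0.5 * (_LOG_2PI + np.log(sig2))
                          - 0.5 * (exp_ds.exposure - mean) ** 2 / sig2))
    lp = config.learning_rate * partial_ll + ll_exp
    lp += log_eppf(part.sizes, ds.n, gp.gamma)
    cpri = config.concentration_prior
    lp += float(gamma_dist.logpdf(gp.gamma, cpri.a_gamma, scale=1.0 / cpri.b_gamma))
    lp += _log_beta_prior(gp.beta_a, gp.beta_z, gp.beta_v, config)
    if exp_ds.z.shape[1]:
        m_z, v_z = pri.alpha_z_prior(exp_ds.z.shape[1])
        lp += float(np.sum(norm_dist.logpdf(gp.alpha_z, m_z, np.sqrt(v_z))))
    for k in range(part.n_clusters):
        if "alpha0" in config.cluster_specific:
            lp += float(norm_dist.logpdf(cp.alpha0[k], pri.m_alpha0,
                                         np.sqrt(pri.tau2_alpha0)))
        if exp_ds.v.shape[1]:
            m_v, v_v = pri.alpha_v_prior(exp_ds.v.shape[1])
            lp += float(np.sum(norm_dist.logpdf(cp.alpha_v[k], m_v, np.sqrt(v_v))))
        if "sigma2" in config.cluster_specific:
            lp += float(invgamma.logpdf(cp.sigma2[k], pri.a_sigma, scale=pri.b_sigma))
    if "sigma2" not in config.cluster_specific:
        lp += float(invgamma.logpdf(cp.sigma2[0], pri.a_sigma, scale=pri.b_sigma))
    return lp


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95,
                        n_groups: "int | str" = 2) -> dict:
    """Posterior means, equal-tailed credible intervals, HR scale, clustering.

    The hazard-ratio summary is exp applied to the log-scale summaries
    (documented convention). ``n_groups`` controls the representative
    clustering (see :func:`representative_clustering`).
    """
    if draws.n_retained < 2:
        raise ValueError("need at least 2 retained draws")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2

    def summ(x):
        return {"mean": float(np.mean(x)),
                "ci_low": float(np.quantile(x, lo)),
                "ci_high": float(np.quantile(x, hi))}

    out = {"level": level, "beta_a": summ(draws.beta_a), "gamma": summ(draws.gamma)}
    out["hazard_ratio"] = {k: float(np.exp(v)) for k, v in out["beta_a"].items()}
    out["beta_z"] = [summ(draws.beta_z[:, j]) for j in range(draws.beta_z.shape[1])]
    out["beta_v"] = [summ(draws.beta_v[:, j]) for j in range(draws.beta_v.shape[1])]
    out["alpha_z"] = [summ(draws.alpha_z[:, j]) for j in range(draws.alpha_z.shape[1])]
    out["n_clusters_mode"] = int(np.bincount(draws.n_clusters).argmax())
    out["clustering"] = representative_clustering(draws, n_groups).tolist()
    return out


def representative_clustering(draws: PosteriorDraws,
                              n_groups: "int | str" = 2) -> np.ndarray:
    """Group subjects by the posterior median of their cluster's alpha0.

    Each subject's per-draw alpha0 (of its assigned cluster) is reduced to a
    posterior median; subjects are then split into groups at the largest gaps
    of the sorted medians. ``n_groups=2`` (default) is the simple two-group
    split; ``n_groups='modal_k'`` uses the posterior modal cluster count.
    """
    med = np.median(draws.subject_alpha0, axis=0)
    if n_groups == "modal_k":
        g = int(np.bincount(draws.n_clusters).argmax())
    else:
        g = int(n_groups)
    g = max(1, min(g, med.size))
    order = np.argsort(med)
    gaps = np.diff(med[order])
    labels = np.zeros(med.size, dtype=np.int64)
    if g > 1 and gaps.size:
        cut_positions = np.sort(np.argsort(gaps)[-(g - 1):])
        grp = np.zeros(med.size, dtype=np.int64)
        for c in cut_positions:
            grp[c + 1:] += 1
        labels[order] = grp
    return labels
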