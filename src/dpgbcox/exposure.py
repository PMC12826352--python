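"""Cluster-wise normal exposure model and its conjugate Gibbs updates.

Given the latent partition, the exposure of subject i in cluster k follows

    A_i | (s_i = k) ~ N(alpha0_k + z_i' alpha_z + v_i' alpha_v_k, sigma2_k),

with alpha_z shared across clusters (the "common predictor" effect) and
(alpha0_k, alpha_v_k, sigma2_k) cluster-specific, drawn from the DP base
measure G0 = the normal / inverse-gamma priors below. All three full
conditionals are conjugate: a multivariate normal for alpha_z given the
cluster parameters, a normal for (alpha0_k, alpha_v_k) given alpha_z, and an
inverse gamma (shape/scale parameterization, density ∝ x^{-a-1} e^{-b/x})
for sigma2_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crp import PartitionState
from .data import SurvivalDataset

__all__ = [
    "ClusterParams",
    "ExposurePriors",
    "exposure_logdensity",
    "update_alpha_z",
    "update_cluster_coefs",
    "update_sigma2",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ClusterParams:
    """Per-cluster exposure parameters, aligned with PartitionState labels.

    alpha0 : shape (K,); alpha_v : shape (K, p_v); sigma2 : shape (K,), > 0.
    """

    alpha0: np.ndarray
    alpha_v: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.alpha0 = np.atleast_1d(np.asarray(self.alpha0, dtype=float))
        self.alpha_v = np.atleast_2d(np.asarray(self.alpha_v, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if self.alpha_v.shape[0] != self.alpha0.shape[0]:
            self.alpha_v = self.alpha_v.reshape(self.alpha0.shape[0], -1)
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive in every cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.alpha0.shape[0])

    def copy(self) -> "ClusterParams":
        return ClusterParams(self.alpha0.copy(), self.alpha_v.copy(), self.sigma2.copy())

    def subset(self, keep: np.ndarray) -> "ClusterParams":
        return ClusterParams(self.alpha0[keep], self.alpha_v[keep], self.sigma2[keep])


@dataclass
class ExposurePriors:
    """Independent priors on the exposure-model parameters.

    Normal priors on the mean-structure coefficients, inverse-gamma
    (shape ``a_sigma``, scale ``b_sigma``) on each cluster variance. Defaults:
    all prior means 0, prior variances 100, a_sigma = b_sigma = 2.
    """

    m_alpha0: float = 0.0
    tau2_alpha0: float = 100.0
    m_alpha_v: np.ndarray | float = 0.0
    var_alpha_v: np.ndarray | float = 100.0
    m_alpha_z: np.ndarray | float = 0.0
    var_alpha_z: np.ndarray | float = 100.0
    a_sigma: float = 2.0
    b_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.tau2_alpha0 <= 0 or self.a_sigma <= 0 or self.b_sigma <= 0:
            raise ValueError("prior variances and IG parameters must be positive")

    def alpha_v_prior(self, p_v: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.broadcast_to(np.atleast_1d(np.asarray(self.m_alpha_v, float)), (p_v,))
        v = np.broadcast_to(np.atleast_1d(np.asarray(self.var_alpha_v, float)), (p_v,))
        return m.astype(float), v.astype(float)

    def alpha_z_prior(self, p_z: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.broadcast_to(np.atleast_1d(np.asarray(self.m_alpha_z, float)), (p_z,))
        v = np.broadcast_to(np.atleast_1d(np.asarray(self.var_alpha_z, float)), (p_z,))
        return m.astype(float), v.astype(float)

    def draw_cluster(self, p_v: int, rng: np.random.Generator
                     ) -> tuple[float, np.ndarray, float]:
        """One fresh draw of (alpha0, alpha_v, sigma2) from the base measure G0."""
        a0 = rng.normal(self.m_alpha0, np.sqrt(self.tau2_alpha0))
        m_v, v_v = self.alpha_v_prior(p_v)
        av = rng.normal(m_v, np.sqrt(v_v)) if p_v else np.zeros(0)
        # IG(a, b) via 1 / Gamma(shape=a, rate=b)
        s2 = 1.0 / rng.gamma(self.a_sigma, 1.0 / self.b_sigma)
        return float(a0), np.atleast_1d(av), float(s2)


def exposure_logdensity(a, z, v, alpha_z, cp: ClusterParams, k: int) -> float:
    """Log normal density of exposure value ``a`` under cluster ``k``."""
    z = np.atleast_1d(np.asarray(z, float))
    v = np.atleast_1d(np.asarray(v, float))
    alpha_z = np.atleast_1d(np.asarray(alpha_z, float))
    if z.shape[0] != alpha_z.shape[0] or v.shape[0] != cp.alpha_v.shape[1]:
        raise ValueError("covariate / coefficient dimension mismatch")
    mean = cp.alpha0[k] + z @ alpha_z + v @ cp.alpha_v[k]
    s2 = cp.sigma2[k]
    return float(-0.5 * (_LOG_2PI + np.log(s2)) - 0.5 * (a - mean) ** 2 / s2)


def _mvn_draw(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(mean.shape[0])


def update_alpha_z(
    ds: SurvivalDataset,
    part: PartitionState,
    cp: ClusterParams,
    prior: ExposurePriors,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact conjugate draw of the shared coefficient alpha_z.

    The full conditional is the posterior of a heteroscedastic weighted
    regression of A - alpha0_{s_i} - v_i' alpha_v_{s_i} on Z with per-subject
    variance sigma2_{s_i}.
    """
    p_z = ds.z.shape[1]
    if p_z == 0:
        raise ValueError("alpha_z update requires dim Z >= 1")
    s = part.assignments
    resid = ds.exposure - cp.alpha0[s] - np.einsum("ij,ij->i", ds.v, cp.alpha_v[s])
    w = 1.0 / cp.sigma2[s]
    m0, v0 = prior.alpha_z_prior(p_z)
    prec = np.diag(1.0 / v0) + (ds.z * w[:, None]).T @ ds.z
    rhs = m0 / v0 + ds.z.T @ (w * resid)
    cov = np.linalg.inv(prec)
    cond = np.linalg.cond(prec)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"alpha_z posterior precision is near-singular (cond={cond:.3g})")
    return _mvn_draw(cov @ rhs, cov, rng)


def update_cluster_coefs(
    ds: SurvivalDataset,
    part: PartitionState,
    alpha_z: np.ndarray,
    prior: ExposurePriors,
    rng: np.random.Generator,
    k: int,
    sigma2_k: float,
) -> tuple[float, np.ndarray]:
    """Exact conjugate joint draw of (alpha0_k, alpha_v_k) for a nonempty cluster."""
    idx = np.flatnonzero(part.assignments == k)
    if idx.size == 0:
        raise ValueError(f"cluster {k} is empty")
    p_v = ds.v.shape[1]
    y = ds.exposure[idx] - ds.z[idx] @ np.atleast_1d(alpha_z)
    design = np.column_stack([np.ones(idx.size), ds.v[idx]])
    m_v, v_v = prior.alpha_v_prior(p_v)
    m0 = np.concatenate([[prior.m_alpha0], m_v])
    v0 = np.concatenate([[prior.tau2_alpha0], v_v])
    prec = np.diag(1.0 / v0) + design.T @ design / sigma2_k
    rhs = m0 / v0 + design.T @ y / sigma2_k
    cov = np.linalg.inv(prec)
    draw = _mvn_draw(cov @ rhs, cov, rng)
    return float(draw[0]), draw[1:]


def update_sigma2(
    ds: SurvivalDataset,
    part: PartitionState,
    alpha_z: np.ndarray,
    cp: ClusterParams,
    prior: ExposurePriors,
    rng: np.random.Generator,
    k: int,
) -> float:
    """Exact IG(a + N_k/2, b + RSS_k/2) draw of the cluster-k residual variance."""
    idx = np.flatnonzero(part.assignments == k)
    if idx.size == 0:
        raise ValueError(f"cluster {k} is empty")
    mean = cp.alpha0[k] + ds.z[idx] @ np.atleast_1d(alpha_z) + ds.v[idx] @ cp.alpha_v[k]
    rss = float(np.sum((ds.exposure[idx] - mean) ** 2))
    shape = prior.a_sigma + idx.size / 2.0
    scale = prior.b_sigma + rss / 2.0
    return float(1.0 / rng.gamma(shape, 1.0 / scale))
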