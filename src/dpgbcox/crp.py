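"""Chinese-restaurant-process partition prior and concentration-parameter update.

The Dirichlet process with precision ``gamma`` induces an exchangeable random
partition of the n subjects. Sequentially, subject i joins an existing cluster
k with probability N_k / (i - 1 + gamma) and opens a new cluster with
probability gamma / (i - 1 + gamma). The joint probability of an assignment
sequence (the EPPF, up to the labelling) is the product of these conditionals
and depends only on the multiset of cluster sizes.

The concentration parameter is given a Gamma(a, b) prior and updated with the
Escobar–West auxiliary-variable scheme, which draws exactly from the full
conditional  p(gamma | K, n) ∝ Ga(gamma; a, b) gamma^K Gamma(gamma) / Gamma(gamma + n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PartitionState",
    "ConcentrationPrior",
    "crp_conditional",
    "log_eppf",
    "sample_gamma",
]


@dataclass
class ConcentrationPrior:
    """Gamma(shape a_gamma, rate b_gamma) prior on the DP precision."""

    a_gamma: float = 1.0
    b_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.a_gamma <= 0 or self.b_gamma <= 0:
            raise ValueError("Gamma prior parameters must be strictly positive")


@dataclass
class PartitionState:
    """Latent cluster assignments with contiguous labels 0..K-1.

    ``assignments`` uses 0-based labels internally; ``sizes`` is aligned with
    the labels and always sums to n with every entry >= 1.
    """

    assignments: np.ndarray
    sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=np.int64)
        if a.size and (a.min() < 0 or not np.array_equal(
                np.unique(a), np.arange(a.max() + 1))):
            a = self.relabel(a)
        self.assignments = a
        self.sizes = np.bincount(a) if a.size else np.zeros(0, dtype=np.int64)

    @staticmethod
    def relabel(a: np.ndarray) -> np.ndarray:
        """Compact arbitrary integer labels to 0..K-1 in order of first appearance."""
        _, inv = np.unique(a, return_inverse=True)
        order = {}
        out = np.empty_like(a)
        nxt = 0
        for i, lab in enumerate(a):
            if lab not in order:
                order[lab] = nxt
                nxt += 1
            out[i] = order[lab]
        return out

    @property
    def n(self) -> int:
        return int(self.assignments.shape[0])

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.shape[0])

    def copy(self) -> "PartitionState":
        return PartitionState(self.assignments.copy())


def crp_conditional(sizes, gamma: float) -> np.ndarray:
    """Predictive probabilities for the next subject: (N_1, ..., N_K, gamma) / (m + gamma).

    ``sizes`` may be empty (first subject), in which case the new-cluster
    probability is 1.
    """
    if gamma <= 0:
        raise ValueError("gamma must be strictly positive")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size and np.any(sizes < 1):
        raise ValueError("cluster sizes must all be >= 1")
    m = sizes.sum()
    return np.append(sizes, gamma) / (m + gamma)


def log_eppf(sizes, n: int, gamma: float) -> float:
    """Log joint probability of an assignment sequence with the given cluster sizes.

    Equals the sum of log sequential CRP conditionals along any order compatible
    with the sizes:  K log(gamma) + sum_k log((N_k - 1)!) - log((gamma)_n)
    with (gamma)_n the rising factorial gamma(gamma+1)...(gamma+n-1).
    """
    if gamma <= 0:
        raise ValueError("gamma must be strictly positive")
    sizes = np.asarray(sizes, dtype=float)
    if int(sizes.sum()) != n:
        raise ValueError(f"sizes sum to {int(sizes.sum())}, expected n={n}")
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must all be >= 1")
    k = sizes.size
    return float(
        k * np.log(gamma)
        + gammaln(sizes).sum()
        + gammaln(gamma)
        - gammaln(gamma + n)
    )


def sample_gamma(
    K: int,
    n: int,
    gamma_current: float,
    prior: ConcentrationPrior,
    rng: np.random.Generator,
) -> float:
    """One Escobar–West auxiliary-variable draw of the DP precision.

    Draw eta ~ Beta(gamma + 1, n), then gamma from the two-component gamma
    mixture  pi * Ga(a + K, b - log eta) + (1 - pi) * Ga(a + K - 1, b - log eta)
    with odds pi/(1-pi) = (a + K - 1) / (n (b - log eta)). The stationary law
    is exactly the full conditional of gamma given the cluster count K.
    """
    if not (1 <= K <= n):
        raise ValueError("need 1 <= K <= n")
    if gamma_current <= 0:
        raise ValueError("gamma_current must be positive")
    a, b = prior.a_gamma, prior.b_gamma
    eta = rng.beta(gamma_current + 1.0, n)
    b_post = b - np.log(eta)
    odds = (a + K - 1.0) / (n * b_post)
    pi_first = odds / (1.0 + odds)
    if rng.uniform() < pi_first:
        shape = a + K
    else:
        shape = a + K - 1.0
    # shape can hit 0 only if a + K = 1, excluded by a > 0, K >= 1
    return float(rng.gamma(shape, 1.0 / b_post))
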