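"""Probabilistic core: emission densities and the auto-logistic MRF.

The model couples, for every SNP t, a vector of binary association
indicators e_t = (e_1t, ..., e_nt) through a pairwise Markov random field
on the phenotype graph G:

    p(e_t | alpha, beta, G) = C(alpha, beta, G) *
        exp( sum_i alpha_i e_it + sum_{i~j} beta_ij e_it e_jt )

where i~j runs over the edges of G and C is the normalizing constant,
computed here by exact enumeration of the 2^n joint states.  Observed
probit scores y_it = Phi^-1(1 - p_it) are emitted from a standard normal
under e_it = 0 and from a log-normal LN(mu_i, sigma_i^2) (log-scale
parameters; mean exp(mu + sigma^2/2)) under e_it = 1.  The log-normal has
support (0, inf), so a score y_it <= 0 forces e_it = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "PhenotypeGraph",
    "ModelParams",
    "LatentField",
    "NormalizerCapError",
    "emission_logdensity",
    "signal_mean",
    "signal_sd",
    "enumerate_states",
    "mrf_log_normalizer",
    "mrf_logprob",
    "conditional_assoc_prob",
    "sufficient_stats",
]

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: enumeration guard: the normalizer sums 2^n states
DEFAULT_N_CAP = 20


class NormalizerCapError(ValueError):
    """Raised when n exceeds the exact-enumeration cap for the normalizer."""


@dataclass
class PhenotypeGraph:
    """Undirected simple graph over ``n`` phenotypes (binary adjacency)."""

    n: int
    adj: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.adj is None:
            self.adj = np.zeros((self.n, self.n), dtype=bool)
        else:
            self.adj = np.asarray(self.adj, dtype=bool).copy()
            if self.adj.shape != (self.n, self.n):
                raise ValueError("adjacency shape does not match n")
            if not np.array_equal(self.adj, self.adj.T):
                raise ValueError("adjacency must be symmetric")
            if self.adj.diagonal().any():
                raise ValueError("adjacency diagonal must be zero")

    @classmethod
    def from_edges(cls, n: int, edges) -> "PhenotypeGraph":
        g = cls(n)
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops not allowed")
            g.adj[i, j] = g.adj[j, i] = True
        return g

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adj, 1).sum())

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adj, 1))
        return list(zip(ii.tolist(), jj.tolist()))

    def copy(self) -> "PhenotypeGraph":
        return PhenotypeGraph(self.n, self.adj)


@dataclass
class ModelParams:
    """One full parameter configuration (alpha, beta, mu, sigma2, G).

    ``beta`` is stored densely symmetric with structural zeros wherever the
    graph has no edge; the spike at zero of the edge prior lives in the
    adjacency, not in a numeric sentinel.
    """

    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    graph: PhenotypeGraph

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        n = self.graph.n
        if self.alpha.shape != (n,) or self.mu.shape != (n,) or self.sigma2.shape != (n,):
            raise ValueError("parameter vectors must have length n")
        if self.beta.shape != (n, n):
            raise ValueError("beta must be n x n")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if np.any(self.beta[~self.graph.adj] != 0):
            # zero diagonal and zero off-graph couplings
            raise ValueError("beta must vanish off the graph")

    def copy(self) -> "ModelParams":
        return ModelParams(self.alpha.copy(), self.beta.copy(), self.mu.copy(),
                           self.sigma2.copy(), self.graph.copy())


@dataclass
class LatentField:
    """T x n binary association indicators, one row per SNP."""

    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e)
        if not np.isin(self.e, (0, 1)).all():
            raise ValueError("field entries must be binary")
        self.e = self.e.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.e.shape


def emission_logdensity(y, e, mu, sigma2):
    """Log density of a probit score under the null (e=0) or signal (e=1).

    Null: standard normal.  Signal: log-normal with log-scale parameters
    ``(mu, sigma2)``; -inf for y <= 0.  Vectorized over all arguments.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    null = -LOG_SQRT_2PI - 0.5 * y**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ly = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
        sig = np.where(
            y > 0,
            -ly - LOG_SQRT_2PI - 0.5 * np.log(sigma2) - (ly - mu) ** 2 / (2.0 * sigma2),
            -np.inf,
        )
    out = np.where(e == 1, sig, null)
    if out.ndim == 0:
        return float(out)
    return out


def signal_mean(mu, sigma2):
    """Mean exp(mu + sigma2/2) of the signal-score (log-normal) component."""
    return np.exp(np.asarray(mu, dtype=float) + np.asarray(sigma2, dtype=float) / 2.0)


def signal_sd(mu, sigma2):
    """Standard deviation of the signal-score component on the y scale."""
    sigma2 = np.asarray(sigma2, dtype=float)
    return signal_mean(mu, sigma2) * np.sqrt(np.expm1(sigma2))


@lru_cache(maxsize=8)
def enumerate_states(n: int, cap: int = DEFAULT_N_CAP) -> np.ndarray:
    """All 2^n binary configurations as a (2^n, n) float matrix.

    Enumeration order: state k has bit i = (k >> i) & 1, i.e. phenotype 0
    is the fastest-varying bit.
    """
    if n > cap:
        raise NormalizerCapError(
            f"exact normalizer enumerates 2^n states; n={n} exceeds cap {cap} "
            "— reduce the number of phenotypes"
        )
    k = np.arange(2**n, dtype=np.int64)
    return ((k[:, None] >> np.arange(n)) & 1).astype(float)


def _state_energies(alpha: np.ndarray, beta: np.ndarray, cap: int = DEFAULT_N_CAP) -> np.ndarray:
    """Unnormalized log-weight of every joint state."""
    n = len(alpha)
    S = enumerate_states(n, cap)
    # beta is symmetric with zero diagonal; the quadratic form double-counts pairs
    return S @ alpha + 0.5 * np.einsum("ki,ij,kj->k", S, beta, S)


def mrf_log_normalizer(params: ModelParams, cap: int = DEFAULT_N_CAP) -> float:
    """log sum over all 2^n states of the unnormalized MRF weight (= -log C)."""
    return float(logsumexp(_state_energies(params.alpha, params.beta, cap)))


def mrf_logprob(e_vec, params: ModelParams) -> float:
    """Exact log probability of one joint association configuration."""
    e = np.asarray(e_vec, dtype=float)
    if e.shape != (params.graph.n,):
        raise ValueError("configuration length must equal n")
    energy = float(e @ params.alpha + 0.5 * e @ params.beta @ e)
    return energy - mrf_log_normalizer(params)


def conditional_assoc_prob(i: int, y_it, e_others, params: ModelParams):
    """P(e_it = 1 | e_-it, y_it): the sampler's single-site conditional.

    logistic( alpha_i + sum_{j~i} beta_ij e_jt + log LN(y) - log N(y;0,1) );
    exactly 0 for y_it <= 0.
    """
    e = np.asarray(e_others, dtype=float)
    y = np.asarray(y_it, dtype=float)
    neigh = e @ params.beta[:, i] - e[..., i] * params.beta[i, i]
    llr = emission_logdensity(y, 1, params.mu[i], params.sigma2[i]) - emission_logdensity(
        y, 0, params.mu[i], params.sigma2[i]
    )
    with np.errstate(invalid="ignore"):
        p = np.where(y > 0, expit(params.alpha[i] + neigh + llr), 0.0)
    if p.ndim == 0:
        return float(p)
    return p


def sufficient_stats(field: LatentField, graph: PhenotypeGraph):
    """Per-phenotype counts S_i = sum_t e_it and pair counts S_ij = sum_t e_it e_jt.

    S_ij is returned for ALL unordered pairs (dense symmetric matrix), not
    only current edges, because reversible-jump birth proposals need counts
    for absent edges too.
    """
    e = field.e
    if e.shape[1] != graph.n:
        raise ValueError("field width must equal number of phenotypes")
    ef = e.astype(np.float64)
    S = ef.sum(axis=0)
    Spair = ef.T @ ef
    np.fill_diagonal(Spair, 0.0)
    return S, Spair
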