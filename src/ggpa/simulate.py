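"""Synthetic GWAS summary statistics with known pleiotropic structure.

The generator reproduces the statistical structure of the model's
benchmark simulation: association indicators for T independent SNPs are
drawn from the auto-logistic MRF on a known phenotype graph by Gibbs
sampling, and probit scores are then emitted from phenotype-specific
normal signal distributions N(mu_i, sigma_i^2) for associated SNPs versus
the standard normal null, finally converted to p-values p = 1 - Phi(y).

Note the deliberate mild misspecification relative to the fitted model:
the signal scores are generated from a normal distribution, while the
model's signal component is log-normal.  Setting ``lognormal_signal``
instead draws signal scores from the log-normal family moment-matched to
(mu_i, sigma_i), for exact model-match experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data_io import SummaryStatMatrix
from .mrf import LatentField, PhenotypeGraph

__all__ = ["SimScenario", "default_scenario", "simulate_efield", "simulate_pvalues",
           "simulate_dataset"]


@dataclass
class SimScenario:
    """Generating configuration: graph, MRF coefficients, signal moments.

    ``mu`` and ``sigma`` are the mean and standard deviation of the signal
    score distribution (y scale).
    """

    graph: PhenotypeGraph
    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    T: int = 20000
    gibbs_iters: int = 1000
    seed: int = 0
    lognormal_signal: bool = False
    phenotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.graph.n
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.beta[~self.graph.adj] != 0) or np.any(self.beta[self.graph.adj] == 0):
            raise ValueError("beta must be nonzero exactly on the edges")
        if not self.phenotypes:
            self.phenotypes = [f"P{i + 1}" for i in range(n)]

    def to_json(self) -> str:
        d = asdict(self)
        d["graph"] = {"n": self.graph.n, "edges": [list(e) for e in self.graph.edges()]}
        for k in ("alpha", "beta", "mu", "sigma"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=1)


def default_scenario(T: int = 20000, seed: int = 0, **kwargs) -> SimScenario:
    """The built-in 7-phenotype benchmark scenario.

    A tightly linked group (P1, P2, P3), a weakly linked group (P3, P4,
    P5) and two isolated negative controls (P6, P7); couplings
    beta_12=4.0, beta_13=1.8, beta_23=2.3, beta_34=2.5, beta_45=5.0, with
    baseline propensities and signal strengths chosen to mimic real GWAS
    p-value distributions.
    """
    n = 7
    edges = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]
    graph = PhenotypeGraph.from_edges(n, edges)
    beta = np.zeros((n, n))
    for (i, j), b in zip(edges, (4.0, 1.8, 2.3, 2.5, 5.0)):
        beta[i, j] = beta[j, i] = b
    return SimScenario(
        graph=graph,
        alpha=np.array([-4.7, -3.0, -5.5, -4.8, -3.6, -2.5, -3.5]),
        beta=beta,
        mu=np.array([1.1, 1.0, 1.2, 1.2, 1.3, 1.1, 1.3]),
        sigma=np.array([0.4, 0.3, 0.35, 0.3, 0.45, 0.4, 0.3]),
        T=T,
        seed=seed,
        **kwargs,
    )


def simulate_efield(scenario: SimScenario, rng: np.random.Generator) -> LatentField:
    """Draw the T x n association field from the MRF by Gibbs sampling.

    All SNPs evolve in parallel (they are independent under the MRF);
    each sweep is a systematic scan over phenotypes starting from the
    all-zero configuration.
    """
    n = scenario.graph.n
    e = np.zeros((scenario.T, n), dtype=np.int8)
    ef = e.astype(np.float64)
    for _ in range(scenario.gibbs_iters):
        for i in range(n):
            p = expit(scenario.alpha[i] + ef @ scenario.beta[:, i])
            col = rng.random(scenario.T) < p
            e[:, i] = col
            ef[:, i] = col
    return LatentField(e)


def simulate_pvalues(
    field: LatentField, scenario: SimScenario, rng: np.random.Generator
) -> SummaryStatMatrix:
    """Emit probit scores given the field and convert to p-values.

    y_it ~ N(mu_i, sigma_i^2) when e_it = 1 and N(0, 1) otherwise;
    p_it = 1 - Phi(y_it).  The returned matrix carries the true field in
    ``truth`` for evaluation.
    """
    T, n = field.shape
    if n != scenario.graph.n:
        raise ValueError("field width does not match scenario")
    y = rng.standard_normal((T, n))
    assoc = field.e == 1
    if scenario.lognormal_signal:
        # log-scale parameters moment-matched to (mu, sigma) on the y scale
        s2 = np.log1p((scenario.sigma / scenario.mu) ** 2)
        m = np.log(scenario.mu) - s2 / 2.0
        signal = np.exp(m + np.sqrt(s2) * rng.standard_normal((T, n)))
    else:
        signal = scenario.mu + scenario.sigma * rng.standard_normal((T, n))
    y = np.where(assoc, signal, y)
    p = norm.sf(y)
    snp_ids = [f"snp{t + 1:06d}" for t in range(T)]
    return SummaryStatMatrix.from_pvalues(
        snp_ids, list(scenario.phenotypes), p, truth=field.e
    )


def simulate_dataset(scenario: SimScenario, seed: int | None = None) -> SummaryStatMatrix:
    """Field generation plus score emission under one seeded stream."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    field = simulate_efield(scenario, rng)
    return simulate_pvalues(field, scenario, rng)
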