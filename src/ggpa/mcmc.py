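"""Posterior sampling for the pleiotropy MRF model.

One sweep of the Metropolis-Hastings-within-Gibbs sampler consists of

1. a systematic-scan Gibbs pass over the latent association field
   (vectorized over SNPs, which are conditionally independent),
2. conjugate Gibbs draws of the signal parameters (mu_i, sigma_i^2),
3. a Gaussian random-walk Metropolis update of each baseline alpha_i,
4. a log-scale random-walk Metropolis update of each coupling beta_ij on
   a current edge, and
5. one (configurable) reversible-jump birth/death toggle of a graph edge,
   with the coupling of a proposed edge drawn from its Gamma prior so that
   prior and proposal densities cancel in the acceptance ratio.

The independence baseline ("independent mode") fixes the empty graph and
skips steps 4-5, which reduces the model to separate per-phenotype
two-group analyses.

The exact MRF normalizer (2^n-state enumeration) is shared across kernels
through a small cache that applies rank-one energy updates per proposal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp, gammaln

from .data_io import SummaryStatMatrix
from .mrf import (
    LOG_SQRT_2PI,
    LatentField,
    ModelParams,
    PhenotypeGraph,
    enumerate_states,
    sufficient_stats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "MCMCConfig",
    "ChainArchive",
    "NormalizerCache",
    "gibbs_update_efield",
    "update_signal_params",
    "update_alpha",
    "update_beta",
    "rjmcmc_graph_move",
    "run_mcmc",
    "initialize_state",
]


@dataclass
class Hyperparams:
    """Prior hyperparameters (weakly informative defaults).

    mu_i ~ N(theta_mu, tau2_mu); sigma_i^2 ~ InvGamma(a_sigma, b_sigma);
    alpha_i ~ N(theta_alpha, tau2_alpha); beta_ij | edge ~ Gamma(a_beta, b_beta)
    (rate parameterization: mean a/b = 2, variance a/b^2 = 1); graph prior
    p(G) proportional to 1/max(|E|, 1), favoring sparse graphs.
    """

    theta_mu: float = 0.0
    tau2_mu: float = 10000.0
    theta_alpha: float = 0.0
    tau2_alpha: float = 10000.0
    a_sigma: float = 0.5
    b_sigma: float = 0.5
    a_beta: float = 4.0
    b_beta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tau2_mu", "tau2_alpha", "a_sigma", "b_sigma", "a_beta", "b_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MCMCConfig:
    n_burnin: int = 10000
    n_main: int = 40000
    thin: int = 1
    seed: int = 0
    independent_mode: bool = False
    proposal_sd_alpha: float = 0.1
    proposal_sd_beta: float = 0.2
    graph_move_per_iter: int = 10
    n_cap: int = 20
    store_field: bool = False
    adapt_during_burnin: bool = False

    def __post_init__(self) -> None:
        if self.n_main <= 0 or self.n_burnin < 0 or self.thin <= 0:
            raise ValueError("iteration counts must be positive")


class NormalizerCache:
    """Exact MRF log-normalizer with O(2^n) incremental proposal evaluation.

    Maintains the vector of unnormalized log-weights (energies) of all
    joint states for the current (alpha, beta) and recomputes the log
    normalizer after a single-parameter perturbation without rebuilding
    the quadratic form.
    """

    def __init__(self, params: ModelParams, cap: int = 20):
        self.S = enumerate_states(params.graph.n, cap)
        self.energies = self.S @ params.alpha + 0.5 * np.einsum(
            "ki,ij,kj->k", self.S, params.beta, self.S
        )
        self._logz: float | None = None
        self._pair_cols: dict[tuple[int, int], np.ndarray] = {}

    @property
    def logz(self) -> float:
        if self._logz is None:
            self._logz = float(logsumexp(self.energies))
        return self._logz

    def _pair(self, i: int, j: int) -> np.ndarray:
        key = (min(i, j), max(i, j))
        col = self._pair_cols.get(key)
        if col is None:
            col = self.S[:, key[0]] * self.S[:, key[1]]
            self._pair_cols[key] = col
        return col

    def trial_alpha(self, i: int, delta: float) -> tuple[float, np.ndarray]:
        e = self.energies + delta * self.S[:, i]
        return float(logsumexp(e)), e

    def trial_beta(self, i: int, j: int, delta: float) -> tuple[float, np.ndarray]:
        e = self.energies + delta * self._pair(i, j)
        return float(logsumexp(e)), e

    def commit(self, logz: float, energies: np.ndarray) -> None:
        self.energies = energies
        self._logz = logz


def _signal_logdensity_col(logy, lognull_col, ypos, mu_i: float, s2_i: float):
    """Log-density of the signal component for one phenotype column."""
    out = np.full(logy.shape, -np.inf)
    out[ypos] = (
        -logy[ypos] - LOG_SQRT_2PI - 0.5 * np.log(s2_i)
        - (logy[ypos] - mu_i) ** 2 / (2.0 * s2_i)
    )
    return out


def gibbs_update_efield(
    field: LatentField,
    data: SummaryStatMatrix,
    params: ModelParams,
    rng: np.random.Generator,
    _cache=None,
) -> LatentField:
    """One systematic-scan Gibbs pass over the T x n association field.

    SNPs are conditionally independent given the parameters, so each
    phenotype column is redrawn for all SNPs at once from the single-site
    conditional; scores y <= 0 keep probability exactly zero.
    """
    e = field.e
    T, n = e.shape
    if _cache is None:
        y = data.y
        ypos = y > 0
        logy = np.where(ypos, np.log(np.where(ypos, y, 1.0)), 0.0)
        lognull = -LOG_SQRT_2PI - 0.5 * y**2
    else:
        logy, lognull, ypos = _cache
    ef = e.astype(np.float64)
    for i in range(n):
        pos = ypos[:, i]
        logsig = _signal_logdensity_col(logy[:, i], lognull[:, i], pos, params.mu[i], params.sigma2[i])
        neigh = ef @ params.beta[:, i]
        logits = params.alpha[i] + neigh[pos] + logsig[pos] - lognull[pos, i]
        p = expit(logits)
        new_col = np.zeros(T, dtype=np.int8)
        new_col[pos] = rng.random(pos.sum()) < p
        e[:, i] = new_col
        ef[:, i] = new_col
    return field


def update_signal_params(
    field: LatentField,
    data: SummaryStatMatrix,
    params: ModelParams,
    hyper: Hyperparams,
    rng: np.random.Generator,
    _logy=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Gibbs draws of (mu_i, sigma_i^2) given the current field.

    With z = {log y_it : e_it = 1} of size m: mu_i is drawn from the
    precision-weighted normal full conditional, sigma_i^2 from
    InvGamma(a + m/2, b + 0.5 * sum (z - mu_i)^2); with m = 0 both come
    from their priors.
    """
    if _logy is None:
        _logy = np.where(data.y > 0, np.log(np.where(data.y > 0, data.y, 1.0)), 0.0)
    n = params.graph.n
    for i in range(n):
        mask = field.e[:, i] == 1
        m = int(mask.sum())
        if m == 0:
            mu_i = rng.normal(hyper.theta_mu, np.sqrt(hyper.tau2_mu))
            s2_i = 1.0 / rng.gamma(hyper.a_sigma, 1.0 / hyper.b_sigma)
        else:
            z = _logy[mask, i]
            prec = 1.0 / hyper.tau2_mu + m / params.sigma2[i]
            mean = (hyper.theta_mu / hyper.tau2_mu + z.sum() / params.sigma2[i]) / prec
            mu_i = rng.normal(mean, np.sqrt(1.0 / prec))
            ssq = float(np.sum((z - mu_i) ** 2))
            s2_i = 1.0 / rng.gamma(hyper.a_sigma + m / 2.0, 1.0 / (hyper.b_sigma + 0.5 * ssq))
        params.mu[i] = mu_i
        params.sigma2[i] = s2_i
    return params.mu, params.sigma2


def _alpha_log_ratio(alpha_new, alpha_old, S_i, T, logz_new, logz_old, hyper):
    prior = -((alpha_new - hyper.theta_alpha) ** 2 - (alpha_old - hyper.theta_alpha) ** 2) / (
        2.0 * hyper.tau2_alpha
    )
    return (alpha_new - alpha_old) * S_i - T * (logz_new - logz_old) + prior


def update_alpha(
    i: int,
    S_i: float,
    T: int,
    params: ModelParams,
    hyper: Hyperparams,
    rng: np.random.Generator,
    cache: NormalizerCache,
    proposal_sd: float = 0.1,
) -> bool:
    """Random-walk Metropolis update of the baseline propensity alpha_i."""
    a_old = params.alpha[i]
    a_new = a_old + proposal_sd * rng.standard_normal()
    logz_new, energies = cache.trial_alpha(i, a_new - a_old)
    logr = _alpha_log_ratio(a_new, a_old, S_i, T, logz_new, cache.logz, hyper)
    if np.log(rng.random()) < logr:
        params.alpha[i] = a_new
        cache.commit(logz_new, energies)
        return True
    return False


def _beta_log_ratio(b_new, b_old, S_ij, T, logz_new, logz_old, hyper):
    # Gamma prior ratio plus the log-scale random-walk Jacobian:
    # (a-1) log(b'/b) - b_rate (b'-b) + log(b'/b)
    prior_and_jac = hyper.a_beta * np.log(b_new / b_old) - hyper.b_beta * (b_new - b_old)
    return (b_new - b_old) * S_ij - T * (logz_new - logz_old) + prior_and_jac


def update_beta(
    i: int,
    j: int,
    S_ij: float,
    T: int,
    params: ModelParams,
    hyper: Hyperparams,
    rng: np.random.Generator,
    cache: NormalizerCache,
    proposal_sd: float = 0.2,
) -> bool:
    """Positivity-preserving (log-scale) Metropolis update of beta_ij on an edge."""
    if not params.graph.adj[i, j]:
        raise RuntimeError("update_beta called on a non-edge")
    b_old = params.beta[i, j]
    b_new = b_old * np.exp(proposal_sd * rng.standard_normal())
    logz_new, energies = cache.trial_beta(i, j, b_new - b_old)
    logr = _beta_log_ratio(b_new, b_old, S_ij, T, logz_new, cache.logz, hyper)
    if np.log(rng.random()) < logr:
        params.beta[i, j] = params.beta[j, i] = b_new
        cache.commit(logz_new, energies)
        return True
    return False


def _graph_prior_logratio(k_old: int, k_new: int) -> float:
    # p(G) propto 1/max(|E|, 1)
    return float(np.log(max(k_old, 1)) - np.log(max(k_new, 1)))


def rjmcmc_graph_move(
    params: ModelParams,
    Spair: np.ndarray,
    T: int,
    hyper: Hyperparams,
    rng: np.random.Generator,
    cache: NormalizerCache,
) -> bool:
    """One reversible-jump edge toggle.

    A pair (i, j) is chosen uniformly among all n(n-1)/2 pairs.  A birth
    draws the new coupling from its Gamma(a_beta, b_beta) prior, so prior
    and proposal cancel and the log acceptance ratio reduces to
    beta* S_ij - T * dlog-normalizer + log p(G_new)/p(G_old); a death uses
    the reciprocal ratio.
    """
    n = params.graph.n
    i, j = _draw_pair(n, rng)
    k = params.graph.n_edges
    if not params.graph.adj[i, j]:
        b_star = rng.gamma(hyper.a_beta, 1.0 / hyper.b_beta)
        logz_new, energies = cache.trial_beta(i, j, b_star)
        logr = b_star * Spair[i, j] - T * (logz_new - cache.logz) + _graph_prior_logratio(k, k + 1)
        if np.log(rng.random()) < logr:
            params.graph.adj[i, j] = params.graph.adj[j, i] = True
            params.beta[i, j] = params.beta[j, i] = b_star
            cache.commit(logz_new, energies)
            return True
    else:
        b_old = params.beta[i, j]
        logz_new, energies = cache.trial_beta(i, j, -b_old)
        logr = -b_old * Spair[i, j] - T * (logz_new - cache.logz) + _graph_prior_logratio(k, k - 1)
        if np.log(rng.random()) < logr:
            params.graph.adj[i, j] = params.graph.adj[j, i] = False
            params.beta[i, j] = params.beta[j, i] = 0.0
            cache.commit(logz_new, energies)
            return True
    return False


def _draw_pair(n: int, rng: np.random.Generator) -> tuple[int, int]:
    idx = int(rng.integers(n * (n - 1) // 2))
    # unrank the idx-th unordered pair in lexicographic order
    for i in range(n - 1):
        row = n - 1 - i
        if idx < row:
            return i, i + 1 + idx
        idx -= row
    raise AssertionError("unreachable")


def initialize_state(
    data: SummaryStatMatrix, hyper: Hyperparams, y_init: float = 1.0
) -> tuple[LatentField, ModelParams]:
    """Data-driven starting point: seed the field at the upper score tail.

    e_it <- 1{y_it > y_init}; mu_i, sigma_i^2 from moments of log y over
    the seeded associations (prior-center fallback when empty); alpha_i <-
    logit of the seeded fraction clamped to [-10, -1]; the graph starts
    empty.  The seed is deliberately dense: GWAS signals can be weak
    enough that almost no SNP is individually significant, and a sparse
    seed would start the signal components from (near-)empty sets whose
    full conditionals are the diffuse priors — burn-in prunes an
    over-seeded component far faster than it can recover an empty one.
    """
    T, n = data.T, data.n
    e = (data.y > y_init).astype(np.int8)
    mu = np.full(n, hyper.theta_mu)
    sigma2 = np.ones(n)
    alpha = np.empty(n)
    for i in range(n):
        m = int(e[:, i].sum())
        if m >= 2:
            z = np.log(data.y[e[:, i] == 1, i])
            mu[i] = float(z.mean())
            sigma2[i] = max(float(z.var()), 1e-4)
        elif m == 1:
            mu[i] = float(np.log(data.y[e[:, i] == 1, i][0]))
        frac = m / T
        with np.errstate(divide="ignore"):
            alpha[i] = np.clip(np.log(frac / (1 - frac)) if 0 < frac < 1 else -10.0, -10.0, -1.0)
    graph = PhenotypeGraph(n)
    params = ModelParams(alpha, np.zeros((n, n)), mu, sigma2, graph)
    return LatentField(e), params


@dataclass
class ChainArchive:
    """Post-burn-in posterior draws and accumulated field means.

    The full T x n field is not stored by default; association inference
    only needs the running posterior means of e_it and of e_it * e_jt,
    which are accumulated over every main iteration.
    """

    phenotypes: list[str]
    snp_ids: list[str]
    pairs: list[tuple[int, int]]
    alpha: np.ndarray       # (n_stored, n)
    mu: np.ndarray          # (n_stored, n)
    sigma2: np.ndarray      # (n_stored, n)
    beta: np.ndarray        # (n_stored, n_pairs); 0 when the edge is absent
    edge: np.ndarray        # (n_stored, n_pairs) bool
    emean: np.ndarray       # (T, n) accumulated mean of e_it
    epair_mean: np.ndarray  # (T, n_pairs) accumulated mean of e_it e_jt
    logpost: np.ndarray     # full trace, burn-in included
    n_burnin: int
    n_main: int
    thin: int
    seed: int
    accept: dict
    config: dict
    hyper: dict
    e_draws: np.ndarray | None = None  # (n_stored, T, n) when store_field

    @property
    def n_stored(self) -> int:
        return self.alpha.shape[0]

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def pair_index(self, i, j) -> int:
        key = (min(i, j), max(i, j))
        try:
            return self.pairs.index(key)
        except ValueError:
            raise KeyError(f"unknown phenotype pair {key}") from None

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = dict(
            alpha=self.alpha, mu=self.mu, sigma2=self.sigma2, beta=self.beta,
            edge=self.edge, emean=self.emean, epair_mean=self.epair_mean,
            logpost=self.logpost,
        )
        if self.e_draws is not None:
            arrays["e_draws"] = self.e_draws
        np.savez_compressed(path / "chain.npz", **arrays)
        manifest = dict(
            format="ggpa-chain-v1",
            phenotypes=self.phenotypes,
            snp_ids=self.snp_ids,
            pairs=[list(p) for p in self.pairs],
            n_burnin=self.n_burnin, n_main=self.n_main, thin=self.thin,
            seed=self.seed, accept=self.accept, config=self.config,
            hyper=self.hyper,
            dims=dict(T=len(self.snp_ids), n=self.n, n_stored=self.n_stored),
        )
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "ChainArchive":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("format") != "ggpa-chain-v1":
            raise ValueError(f"not a chain archive: {path}")
        with np.load(path / "chain.npz") as z:
            arrays = {k: z[k] for k in z.files}
        return cls(
            phenotypes=manifest["phenotypes"], snp_ids=manifest["snp_ids"],
            pairs=[tuple(p) for p in manifest["pairs"]],
            alpha=arrays["alpha"], mu=arrays["mu"], sigma2=arrays["sigma2"],
            beta=arrays["beta"], edge=arrays["edge"], emean=arrays["emean"],
            epair_mean=arrays["epair_mean"], logpost=arrays["logpost"],
            n_burnin=manifest["n_burnin"], n_main=manifest["n_main"],
            thin=manifest["thin"], seed=manifest["seed"],
            accept=manifest["accept"], config=manifest["config"],
            hyper=manifest["hyper"], e_draws=arrays.get("e_draws"),
        )


def _log_posterior(data, field, params, hyper, cache, logy, lognull, ypos):
    e = field.e
    T, n = e.shape
    # emission
    ll = 0.0
    for i in range(n):
        logsig = _signal_logdensity_col(logy[:, i], lognull[:, i], ypos[:, i], params.mu[i], params.sigma2[i])
        col = np.where(e[:, i] == 1, logsig, lognull[:, i])
        ll += float(col.sum())
    # MRF
    S, Spair = sufficient_stats(field, params.graph)
    ll += float(S @ params.alpha) + 0.5 * float(np.sum(params.beta * Spair)) - T * cache.logz
    # priors
    ll += float(np.sum(-((params.alpha - hyper.theta_alpha) ** 2) / (2 * hyper.tau2_alpha)))
    ll += float(np.sum(-((params.mu - hyper.theta_mu) ** 2) / (2 * hyper.tau2_mu)))
    ll += float(np.sum(-(hyper.a_sigma + 1) * np.log(params.sigma2) - hyper.b_sigma / params.sigma2))
    edges = params.graph.edges()
    for i, j in edges:
        b = params.beta[i, j]
        ll += (hyper.a_beta - 1) * np.log(b) - hyper.b_beta * b
    ll += len(edges) * (hyper.a_beta * np.log(hyper.b_beta) - gammaln(hyper.a_beta))
    ll -= np.log(max(len(edges), 1))
    return ll


def run_mcmc(
    data: SummaryStatMatrix,
    config: MCMCConfig | None = None,
    hyper: Hyperparams | None = None,
    progress_every: int = 0,
) -> ChainArchive:
    """Run the full sampler and return the posterior archive.

    A single integer seed expands into three independent substreams
    (field, parameters, graph) so the component kernels can be reordered
    without perturbing each other's randomness.
    """
    config = config or MCMCConfig()
    hyper = hyper or Hyperparams()
    T, n = data.T, data.n
    enumerate_states(n, config.n_cap)  # capability guard before any work

    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_params, rng_graph = (np.random.default_rng(s) for s in ss.spawn(3))

    field, params = initialize_state(data, hyper)
    if config.independent_mode:
        params.graph = PhenotypeGraph(n)
        params.beta = np.zeros((n, n))
    cache = NormalizerCache(params, config.n_cap)

    y = data.y
    ypos = y > 0
    logy = np.where(ypos, np.log(np.where(ypos, y, 1.0)), 0.0)
    lognull = -LOG_SQRT_2PI - 0.5 * y**2
    efield_cache = (logy, lognull, ypos)

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    P = len(pairs)
    pi_idx = np.array([p[0] for p in pairs])
    pj_idx = np.array([p[1] for p in pairs])

    n_stored = config.n_main // config.thin
    store = dict(
        alpha=np.empty((n_stored, n)), mu=np.empty((n_stored, n)),
        sigma2=np.empty((n_stored, n)), beta=np.zeros((n_stored, P)),
        edge=np.zeros((n_stored, P), dtype=bool),
    )
    e_draws = np.empty((n_stored, T, n), dtype=np.int8) if config.store_field else None
    emean = np.zeros((T, n))
    epair = np.zeros((T, P))
    total = config.n_burnin + config.n_main
    logpost = np.empty(total)
    acc = dict(alpha=[0, 0], beta=[0, 0], graph=[0, 0])
    sd_alpha, sd_beta = config.proposal_sd_alpha, config.proposal_sd_beta

    stored = 0
    for it in range(total):
        gibbs_update_efield(field, data, params, rng_field, _cache=efield_cache)
        update_signal_params(field, data, params, hyper, rng_params, _logy=logy)
        S, Spair = sufficient_stats(field, params.graph)
        for i in range(n):
            acc["alpha"][1] += 1
            acc["alpha"][0] += update_alpha(i, S[i], T, params, hyper, rng_params, cache, sd_alpha)
        if not config.independent_mode:
            for i, j in params.graph.edges():
                acc["beta"][1] += 1
                acc["beta"][0] += update_beta(i, j, Spair[i, j], T, params, hyper, rng_params, cache, sd_beta)
            for _ in range(config.graph_move_per_iter):
                acc["graph"][1] += 1
                acc["graph"][0] += rjmcmc_graph_move(params, Spair, T, hyper, rng_graph, cache)
        lp = _log_posterior(data, field, params, hyper, cache, logy, lognull, ypos)
        logpost[it] = lp
        if not np.isfinite(lp):
            raise RuntimeError(
                f"non-finite log-posterior at iteration {it}: "
                f"alpha={params.alpha}, mu={params.mu}, sigma2={params.sigma2}, "
                f"edges={params.graph.edges()}"
            )
        if config.adapt_during_burnin and it < config.n_burnin and it > 0 and it % 100 == 0:
            # Robbins-Monro-style scale tuning toward ~0.44 acceptance,
            # frozen at the end of burn-in to preserve detailed balance
            rate_a = acc["alpha"][0] / max(acc["alpha"][1], 1)
            sd_alpha *= np.exp(0.5 * (rate_a - 0.44))
            if acc["beta"][1]:
                rate_b = acc["beta"][0] / acc["beta"][1]
                sd_beta *= np.exp(0.5 * (rate_b - 0.44))
        if it >= config.n_burnin:
            emean += field.e
            epair += field.e[:, pi_idx] * field.e[:, pj_idx]
            k = it - config.n_burnin
            if (k + 1) % config.thin == 0:
                store["alpha"][stored] = params.alpha
                store["mu"][stored] = params.mu
                store["sigma2"][stored] = params.sigma2
                store["beta"][stored] = params.beta[pi_idx, pj_idx]
                store["edge"][stored] = params.graph.adj[pi_idx, pj_idx]
                if e_draws is not None:
                    e_draws[stored] = field.e
                stored += 1
        if progress_every and (it + 1) % progress_every == 0:
            logger.info(
                "iter %d/%d logpost=%.1f edges=%d acc(alpha)=%.2f acc(graph)=%.2f",
                it + 1, total, lp, params.graph.n_edges,
                acc["alpha"][0] / max(acc["alpha"][1], 1),
                acc["graph"][0] / max(acc["graph"][1], 1),
            )

    emean /= config.n_main
    epair /= config.n_main
    accept = {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in acc.items()}
    return ChainArchive(
        phenotypes=list(data.phenotypes), snp_ids=list(data.snp_ids), pairs=pairs,
        alpha=store["alpha"][:stored], mu=store["mu"][:stored],
        sigma2=store["sigma2"][:stored], beta=store["beta"][:stored],
        edge=store["edge"][:stored], emean=emean, epair_mean=epair,
        logpost=logpost, n_burnin=config.n_burnin, n_main=config.n_main,
        thin=config.thin, seed=config.seed, accept=accept,
        config=asdict(config), hyper=asdict(hyper), e_draws=e_draws,
    )
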