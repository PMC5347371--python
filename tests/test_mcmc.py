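import itertools

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import gamma as gamma_dist, invgamma, norm

from conftest import random_params
from ggpa.data_io import SummaryStatMatrix
from ggpa.mcmc import (
    ChainArchive,
    Hyperparams,
    MCMCConfig,
    NormalizerCache,
    _alpha_log_ratio,
    _beta_log_ratio,
    gibbs_update_efield,
    initialize_state,
    rjmcmc_graph_move,
    run_mcmc,
    update_alpha,
    update_beta,
    update_signal_params,
)
from ggpa.mrf import (
    LatentField,
    ModelParams,
    NormalizerCapError,
    PhenotypeGraph,
    emission_logdensity,
    mrf_log_normalizer,
    mrf_logprob,
    sufficient_stats,
)


def make_data(pvals, names=None):
    pvals = np.asarray(pvals, dtype=float)
    names = names or [f"P{i+1}" for i in range(pvals.shape[1])]
    return SummaryStatMatrix.from_pvalues(
        [f"s{t}" for t in range(pvals.shape[0])], names, pvals
    )


def make_params(alpha, edges_beta=(), mu=None, sigma2=None):
    n = len(alpha)
    graph = PhenotypeGraph.from_edges(n, [e for e, _ in edges_beta])
    beta = np.zeros((n, n))
    for (i, j), b in edges_beta:
        beta[i, j] = beta[j, i] = b
    return ModelParams(
        np.asarray(alpha, float), beta,
        np.zeros(n) if mu is None else np.asarray(mu, float),
        np.ones(n) if sigma2 is None else np.asarray(sigma2, float),
        graph,
    )


class TestGibbsEfield:
    def test_nonpositive_scores_freeze_field(self):
        rng = np.random.default_rng(0)
        data = make_data(rng.uniform(0.6, 0.99, (30, 3)))  # all y < 0
        field = LatentField(np.zeros((30, 3), dtype=int))
        params = make_params([0.0, 0.0, 0.0])
        for _ in range(20):
            gibbs_update_efield(field, data, params, rng)
        assert field.e.sum() == 0

    def test_long_run_matches_enumeration(self):
        # per-SNP state frequencies vs the exact conditional p(e_t | y_t)
        rng = np.random.default_rng(1)
        params = make_params([-0.5, -1.0], [((0, 1), 1.5)], mu=[0.2, 0.1],
                             sigma2=[0.5, 0.4])
        pv = np.array([[0.05, 0.2], [0.3, 0.02], [0.45, 0.4]])
        data = make_data(pv)
        field = LatentField(np.zeros((3, 2), dtype=int))
        counts = np.zeros((3, 4))
        n_sweeps = 4000
        for s in range(n_sweeps + 100):
            gibbs_update_efield(field, data, params, rng)
            if s >= 100:
                counts[np.arange(3), field.e[:, 0] + 2 * field.e[:, 1]] += 1
        freq = counts / n_sweeps
        for t in range(3):
            w = np.array(
                [
                    np.exp(
                        mrf_logprob([e1, e2], params)
                        + emission_logdensity(data.y[t, 0], e1, params.mu[0], params.sigma2[0])
                        + emission_logdensity(data.y[t, 1], e2, params.mu[1], params.sigma2[1])
                    )
                    for e1, e2 in [(0, 0), (1, 0), (0, 1), (1, 1)]
                ]
            )
            np.testing.assert_allclose(freq[t], w / w.sum(), atol=0.04)

    def test_independent_columns_without_coupling(self):
        rng = np.random.default_rng(2)
        params = make_params([-1.0, -0.5], mu=[0.1, 0.1], sigma2=[0.4, 0.4])
        pv = rng.uniform(0.001, 0.999, (3000, 2))
        data = make_data(pv)
        field = LatentField(np.zeros((3000, 2), dtype=int))
        gibbs_update_efield(field, data, params, rng)
        for i in range(2):
            llr = emission_logdensity(data.y[:, i], 1, params.mu[i], params.sigma2[i]) - \
                emission_logdensity(data.y[:, i], 0, params.mu[i], params.sigma2[i])
            p = np.where(data.y[:, i] > 0, expit(params.alpha[i] + llr), 0.0)
            se = np.sqrt(np.sum(p * (1 - p))) / len(p)
            assert abs(field.e[:, i].mean() - p.mean()) < 4 * se + 1e-9


class TestSignalParams:
    def test_empty_component_samples_prior(self):
        rng = np.random.default_rng(3)
        data = make_data([[0.4, 0.5]])
        field = LatentField(np.zeros((1, 2), dtype=int))
        params = make_params([0.0, 0.0])
        hyper = Hyperparams()
        mus, s2s = [], []
        for _ in range(3000):
            update_signal_params(field, data, params, hyper, rng)
            mus.append(params.mu[0])
            s2s.append(params.sigma2[0])
            params.sigma2[:] = 1.0
        assert abs(np.mean(mus)) < 3 * 100 / np.sqrt(3000)
        assert 80 < np.std(mus) < 120
        expected_med = invgamma(hyper.a_sigma, scale=hyper.b_sigma).median()
        assert np.median(s2s) == pytest.approx(expected_med, rel=0.2)

    def test_single_observation_conditional(self):
        # z = log y = 0, theta_mu=0, tau2_mu=1, sigma2=1 -> mu | . ~ N(0, 1/2)
        rng = np.random.default_rng(4)
        data = make_data([[float(norm.sf(1.0)), 0.5]])  # y = 1 for P1
        field = LatentField(np.array([[1, 0]]))
        hyper = Hyperparams(tau2_mu=1.0)
        draws = []
        for _ in range(4000):
            params = make_params([0.0, 0.0])
            update_signal_params(field, data, params, hyper, rng)
            draws.append(params.mu[0])
        draws = np.array(draws)
        assert abs(draws.mean()) < 4 * np.sqrt(0.5 / 4000)
        assert draws.var() == pytest.approx(0.5, rel=0.1)

    def test_concentrates_on_shared_value(self):
        rng = np.random.default_rng(5)
        c = 0.5
        T = 300
        pv = np.column_stack([np.full(T, float(norm.sf(np.exp(c)))), np.full(T, 0.5)])
        data = make_data(pv)
        field = LatentField(np.column_stack([np.ones(T, int), np.zeros(T, int)]))
        params = make_params([0.0, 0.0])
        hyper = Hyperparams()
        trace = []
        for _ in range(200):
            update_signal_params(field, data, params, hyper, rng)
            trace.append(params.mu[0])
        assert np.mean(trace[100:]) == pytest.approx(c, abs=0.05)


class TestMetropolisRatios:
    def test_alpha_ratio_matches_enumeration(self):
        rng = np.random.default_rng(6)
        params = random_params(2, rng, edge_prob=1.0)
        e = rng.integers(0, 2, (5, 2))
        S, _ = sufficient_stats(LatentField(e), params.graph)
        hyper = Hyperparams(theta_alpha=-1.0, tau2_alpha=2.0)
        i, a_new = 0, 0.7
        params2 = params.copy()
        params2.alpha[i] = a_new
        direct = (
            sum(mrf_logprob(e[t], params2) - mrf_logprob(e[t], params) for t in range(5))
            + norm.logpdf(a_new, hyper.theta_alpha, np.sqrt(hyper.tau2_alpha))
            - norm.logpdf(params.alpha[i], hyper.theta_alpha, np.sqrt(hyper.tau2_alpha))
        )
        got = _alpha_log_ratio(
            a_new, params.alpha[i], S[i], 5,
            mrf_log_normalizer(params2), mrf_log_normalizer(params), hyper,
        )
        assert got == pytest.approx(direct, abs=1e-10)

    def test_beta_ratio_matches_enumeration(self):
        rng = np.random.default_rng(7)
        params = make_params([-0.3, 0.2], [((0, 1), 1.2)])
        e = rng.integers(0, 2, (6, 2))
        _, Spair = sufficient_stats(LatentField(e), params.graph)
        hyper = Hyperparams()
        b_new = 2.1
        params2 = make_params([-0.3, 0.2], [((0, 1), b_new)])
        direct = (
            sum(mrf_logprob(e[t], params2) - mrf_logprob(e[t], params) for t in range(6))
            + gamma_dist.logpdf(b_new, hyper.a_beta, scale=1 / hyper.b_beta)
            - gamma_dist.logpdf(1.2, hyper.a_beta, scale=1 / hyper.b_beta)
            + np.log(b_new / 1.2)  # log-scale random-walk asymmetry
        )
        got = _beta_log_ratio(
            b_new, 1.2, Spair[0, 1], 6,
            mrf_log_normalizer(params2), mrf_log_normalizer(params), hyper,
        )
        assert got == pytest.approx(direct, abs=1e-10)

    def test_null_proposal_always_accepted(self):
        rng = np.random.default_rng(8)
        params = make_params([-1.0, -1.0], [((0, 1), 1.0)])
        cache = NormalizerCache(params)
        assert update_alpha(0, 3.0, 10, params, Hyperparams(), rng, cache, proposal_sd=0.0)
        assert update_beta(0, 1, 3.0, 10, params, Hyperparams(), rng, cache, proposal_sd=0.0)

    def test_beta_requires_edge(self):
        params = make_params([0.0, 0.0])
        cache = NormalizerCache(params)
        with pytest.raises(RuntimeError):
            update_beta(0, 1, 0.0, 10, params, Hyperparams(),
                        np.random.default_rng(0), cache)

    def test_alpha_prior_reproduced_without_data(self):
        rng = np.random.default_rng(9)
        hyper = Hyperparams(tau2_alpha=1.0)
        params = make_params([0.0, 0.0])
        cache = NormalizerCache(params)
        draws = []
        for _ in range(6000):
            update_alpha(0, 0.0, 0, params, hyper, rng, cache, proposal_sd=1.5)
            draws.append(params.alpha[0])
        draws = np.array(draws[500:])
        assert abs(draws.mean()) < 0.1
        assert draws.std() == pytest.approx(1.0, abs=0.1)

    def test_beta_prior_reproduced_without_data(self):
        # stationary law of beta_ij at T=0 is Gamma(4, 2): mean 2, variance 1
        rng = np.random.default_rng(10)
        params = make_params([0.0, 0.0], [((0, 1), 2.0)])
        cache = NormalizerCache(params)
        hyper = Hyperparams()
        draws = []
        for _ in range(8000):
            update_beta(0, 1, 0.0, 0, params, hyper, rng, cache, proposal_sd=1.0)
            draws.append(params.beta[0, 1])
        draws = np.array(draws[500:])
        assert draws.mean() == pytest.approx(2.0, abs=0.15)
        assert draws.var() == pytest.approx(1.0, abs=0.25)


class TestReversibleJump:
    def test_toggles_always_accepted_without_data(self):
        # n=2: a single pair; at T=0 both birth and death have unit ratio
        rng = np.random.default_rng(11)
        params = make_params([0.0, 0.0])
        cache = NormalizerCache(params)
        states = []
        for _ in range(40):
            assert rjmcmc_graph_move(params, np.zeros((2, 2)), 0, Hyperparams(), rng, cache)
            states.append(params.graph.n_edges)
        assert states == [1, 0] * 20

    def test_edge_count_prior_reproduced(self):
        # stationary edge-count law for n=3 under p(G) propto 1/max(|E|,1)
        rng = np.random.default_rng(12)
        params = make_params([0.0, 0.0, 0.0])
        cache = NormalizerCache(params)
        hyper = Hyperparams()
        counts = np.zeros(4)
        for _ in range(30000):
            rjmcmc_graph_move(params, np.zeros((3, 3)), 0, hyper, rng, cache)
            counts[params.graph.n_edges] += 1
        freq = counts / counts.sum()
        # weights: 1 graph at |E|=0 (w 1), 3 at 1 (w 1), 3 at 2 (w 1/2), 1 at 3 (w 1/3)
        expected = np.array([1.0, 3.0, 1.5, 1 / 3])
        expected /= expected.sum()
        np.testing.assert_allclose(freq, expected, atol=0.03)

    def test_strong_coupling_forces_birth(self):
        rng = np.random.default_rng(13)
        hyper = Hyperparams()
        accepted = 0
        for _ in range(20):
            params = make_params([0.0, 0.0])
            cache = NormalizerCache(params)
            Spair = np.zeros((2, 2))
            Spair[0, 1] = Spair[1, 0] = 50.0
            accepted += rjmcmc_graph_move(params, Spair, 50, hyper, rng, cache)
        assert accepted == 20


class TestRunMCMC:
    def test_smoke_bookkeeping(self, smoke_chain):
        assert smoke_chain.n_stored == 150
        assert smoke_chain.emean.shape == (300, 3)
        assert np.all((smoke_chain.emean >= 0) & (smoke_chain.emean <= 1))
        assert np.all((smoke_chain.epair_mean >= 0) & (smoke_chain.epair_mean <= 1))
        assert np.isfinite(smoke_chain.logpost).all()
        assert len(smoke_chain.logpost) == 250

    def test_pairwise_mean_bounded_by_marginals(self, smoke_chain):
        for k, (i, j) in enumerate(smoke_chain.pairs):
            assert np.all(smoke_chain.epair_mean[:, k] <= smoke_chain.emean[:, i] + 1e-12)
            assert np.all(smoke_chain.epair_mean[:, k] <= smoke_chain.emean[:, j] + 1e-12)

    def test_deterministic_given_seed(self, toy_data):
        cfg = MCMCConfig(n_burnin=30, n_main=40, seed=123)
        a = run_mcmc(toy_data, cfg)
        b = run_mcmc(toy_data, cfg)
        for name in ("alpha", "mu", "sigma2", "beta", "emean", "epair_mean", "logpost"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(a.edge, b.edge)

    def test_stored_field_consistent_with_running_mean(self, toy_data):
        cfg = MCMCConfig(n_burnin=20, n_main=60, seed=5, store_field=True)
        chain = run_mcmc(toy_data, cfg)
        np.testing.assert_allclose(chain.e_draws.mean(axis=0), chain.emean, atol=1e-12)

    def test_nonpositive_scores_stay_null(self):
        rng = np.random.default_rng(14)
        data = make_data(rng.uniform(0.55, 0.999, (40, 2)))
        chain = run_mcmc(data, MCMCConfig(n_burnin=20, n_main=30, seed=1))
        assert chain.emean.sum() == 0

    def test_independent_mode_keeps_empty_graph(self, toy_data):
        cfg = MCMCConfig(n_burnin=30, n_main=40, seed=2, independent_mode=True)
        chain = run_mcmc(toy_data, cfg)
        assert not chain.edge.any()
        assert not chain.beta.any()

    def test_capability_error_above_cap(self):
        rng = np.random.default_rng(15)
        data = make_data(rng.uniform(0.01, 0.99, (5, 25)))
        with pytest.raises(NormalizerCapError):
            run_mcmc(data, MCMCConfig(n_burnin=5, n_main=5, seed=0))

    def test_archive_roundtrip(self, smoke_chain, tmp_path):
        smoke_chain.save(tmp_path / "arch")
        back = ChainArchive.load(tmp_path / "arch")
        np.testing.assert_array_equal(back.alpha, smoke_chain.alpha)
        np.testing.assert_array_equal(back.emean, smoke_chain.emean)
        assert back.pairs == smoke_chain.pairs
        assert back.phenotypes == smoke_chain.phenotypes
        assert back.accept == pytest.approx(smoke_chain.accept)


class TestInitialization:
    def test_seeds_only_clear_signals(self):
        pv = np.array([[1e-6, 0.5], [0.3, 1e-5], [0.2, 0.4]])
        field, params = initialize_state(make_data(pv), Hyperparams())
        np.testing.assert_array_equal(field.e, [[1, 0], [0, 1], [0, 0]])
        assert params.graph.n_edges == 0
        assert np.all(params.alpha <= -1.0) and np.all(params.alpha >= -10.0)

    def test_empty_component_falls_back_to_prior_center(self):
        pv = np.full((4, 2), 0.4)
        field, params = initialize_state(make_data(pv), Hyperparams())
        assert field.e.sum() == 0
        np.testing.assert_array_equal(params.mu, [0.0, 0.0])
        np.testing.assert_array_equal(params.sigma2, [1.0, 1.0])
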