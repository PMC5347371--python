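import numpy as np
import pytest
from hypothesis import settings

from ggpa import MCMCConfig, SimScenario, SummaryStatMatrix, run_mcmc, simulate_dataset
from ggpa.mrf import ModelParams, PhenotypeGraph

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_params(n: int, rng: np.random.Generator, edge_prob: float = 0.5) -> ModelParams:
    """Random small MRF parameter configuration for oracle comparisons."""
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            adj[i, j] = adj[j, i] = rng.random() < edge_prob
    graph = PhenotypeGraph(n, adj)
    beta = np.zeros((n, n))
    for i, j in graph.edges():
        beta[i, j] = beta[j, i] = rng.gamma(2.0, 1.0) + 1e-3
    return ModelParams(
        alpha=rng.normal(0, 1.5, n),
        beta=beta,
        mu=rng.normal(0, 0.5, n),
        sigma2=rng.uniform(0.2, 2.0, n),
        graph=graph,
    )


@pytest.fixture(scope="session")
def toy_data() -> SummaryStatMatrix:
    """Small 3-phenotype dataset simulated from a single-edge scenario."""
    graph = PhenotypeGraph.from_edges(3, [(0, 1)])
    beta = np.zeros((3, 3))
    beta[0, 1] = beta[1, 0] = 2.0
    scn = SimScenario(
        graph=graph, alpha=np.array([-2.0, -2.0, -2.5]), beta=beta,
        mu=np.array([1.2, 1.1, 1.0]), sigma=np.array([0.4, 0.4, 0.3]),
        T=300, gibbs_iters=200, seed=7,
    )
    return simulate_dataset(scn)


@pytest.fixture(scope="session")
def smoke_chain(toy_data):
    """Short fitted chain used by bookkeeping and diagnostics tests."""
    cfg = MCMCConfig(n_burnin=100, n_main=150, seed=11)
    return run_mcmc(toy_data, cfg)
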