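"""Posterior summaries: graph calls, coupling summaries, local fdr, global FDR.

Edge calls follow the two-part rule: declare phenotypes i and j correlated
when the posterior edge probability p(E(i,j)|Y) exceeds 0.5 AND the
coupling is significantly positive, p(beta_ij > 0 | Y) > 0.95.  Because
the coupling is positive exactly when the edge is present, the exceedance
probability numerically equals the edge probability; an alternative rule
based on the marginal 95% credible interval excluding zero is provided.

Association mapping controls the global FDR with the direct posterior
probability approach: SNPs are sorted by local fdr (f_it = 1 - p(e_it=1|Y),
pairwise f_ijt = 1 - p(e_it=1, e_jt=1|Y)) and the largest prefix whose
average fdr stays below the nominal bound tau is declared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import ChainArchive
from .mrf import PhenotypeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSummary",
    "AssociationCalls",
    "summarize_edges",
    "declare_edges",
    "local_fdr",
    "control_fdr",
    "call_associations",
    "chain_diagnostics",
    "edges_to_frame",
    "graph_to_dot",
]


@dataclass
class EdgeSummary:
    """Posterior summary of one phenotype pair."""

    i: int
    j: int
    name_i: str
    name_j: str
    post_edge_prob: float
    exceed_prob: float
    beta_mean_marginal: float
    beta_mean_conditional: float
    beta_q025_marginal: float
    beta_q975_marginal: float
    beta_q025_conditional: float
    beta_q975_conditional: float
    selected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.post_edge_prob <= 1.0:
            raise ValueError("post_edge_prob must be a probability")
        if self.exceed_prob > self.post_edge_prob + 1e-12:
            raise ValueError("beta can exceed zero only when the edge is present")


def summarize_edges(chain: ChainArchive) -> list[EdgeSummary]:
    """Per-pair edge probabilities and coupling summaries from stored draws.

    Marginal quantities treat draws with the edge absent as beta = 0 (the
    spike of the prior); conditional quantities use only draws with the
    edge present.
    """
    if chain.n_stored < 1:
        raise ValueError("chain archive has no stored draws")
    out = []
    for k, (i, j) in enumerate(chain.pairs):
        present = chain.edge[:, k]
        b = chain.beta[:, k]
        p_edge = float(present.mean())
        exceed = float((b > 0).mean())
        if present.any():
            bc = b[present]
            cond = (float(bc.mean()), float(np.quantile(bc, 0.025)), float(np.quantile(bc, 0.975)))
        else:
            cond = (float("nan"),) * 3
        out.append(
            EdgeSummary(
                i=i, j=j, name_i=chain.phenotypes[i], name_j=chain.phenotypes[j],
                post_edge_prob=p_edge, exceed_prob=exceed,
                beta_mean_marginal=float(b.mean()), beta_mean_conditional=cond[0],
                beta_q025_marginal=float(np.quantile(b, 0.025)),
                beta_q975_marginal=float(np.quantile(b, 0.975)),
                beta_q025_conditional=cond[1], beta_q975_conditional=cond[2],
            )
        )
    return out


def declare_edges(
    summaries: list[EdgeSummary],
    prob_threshold: float = 0.5,
    exceed_threshold: float = 0.95,
    rule: str = "exceedance",
) -> PhenotypeGraph:
    """Call the phenotype graph from edge summaries (mutates ``selected``).

    rule="exceedance": p(E|Y) > prob_threshold and p(beta>0|Y) > exceed_threshold.
    rule="ci": p(E|Y) > prob_threshold and the marginal 95% credible
    interval of the coupling excludes zero.
    """
    n = max(max(s.i, s.j) for s in summaries) + 1
    g = PhenotypeGraph(n)
    for s in summaries:
        if rule == "exceedance":
            s.selected = s.post_edge_prob > prob_threshold and s.exceed_prob > exceed_threshold
        elif rule == "ci":
            s.selected = s.post_edge_prob > prob_threshold and s.beta_q025_marginal > 0
        else:
            raise ValueError(f"unknown edge rule {rule!r}")
        if s.selected:
            g.adj[s.i, s.j] = g.adj[s.j, s.i] = True
    return g


def local_fdr(chain: ChainArchive, phenotype=None, pair=None) -> np.ndarray:
    """Local false discovery rates over SNPs.

    Marginal (``phenotype`` given): f_it = 1 - p(e_it = 1 | Y).
    Pairwise (``pair`` given): f_ijt = 1 - p(e_it = 1, e_jt = 1 | Y).
    Phenotypes may be given by name or index.
    """
    if (phenotype is None) == (pair is None):
        raise ValueError("give exactly one of phenotype or pair")
    if phenotype is not None:
        i = _resolve(chain, phenotype)
        return 1.0 - chain.emean[:, i]
    i, j = (_resolve(chain, p) for p in pair)
    return 1.0 - chain.epair_mean[:, chain.pair_index(i, j)]


def _resolve(chain: ChainArchive, phenotype) -> int:
    if isinstance(phenotype, str):
        try:
            return chain.phenotypes.index(phenotype)
        except ValueError:
            raise KeyError(f"unknown phenotype {phenotype!r}") from None
    i = int(phenotype)
    if not 0 <= i < chain.n:
        raise KeyError(f"phenotype index {i} out of range")
    return i


def control_fdr(fdr_values, tau: float) -> tuple[np.ndarray, float]:
    """Direct posterior probability control of the global FDR.

    Sort fdr values ascending (stable; ties broken by SNP input order),
    take the largest prefix whose running mean stays <= tau, and call its
    members.  Returns (call flags in input order, threshold kappa); kappa
    is 0 with an empty call set when even the smallest fdr exceeds tau.
    """
    f = np.asarray(fdr_values, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fdr values must lie in [0, 1]")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    order = np.argsort(f, kind="stable")
    cummean = np.cumsum(f[order]) / np.arange(1, len(f) + 1)
    ok = np.nonzero(cummean <= tau)[0]
    called = np.zeros(len(f), dtype=bool)
    if len(ok) == 0:
        return called, 0.0
    k = ok[-1] + 1  # running mean of sorted values is nondecreasing
    called[order[:k]] = True
    return called, float(f[order[k - 1]])


@dataclass
class AssociationCalls:
    """FDR-controlled association calls per phenotype and phenotype pair."""

    tau: float
    snp_ids: list[str]
    per_phenotype: dict = field(default_factory=dict)  # name -> (fdr, called, kappa)
    per_pair: dict = field(default_factory=dict)       # (name_i, name_j) -> (fdr, called, kappa)

    def frame(self, key) -> pd.DataFrame:
        table = self.per_phenotype.get(key) or self.per_pair.get(key)
        if table is None:
            raise KeyError(key)
        fdr, called, _ = table
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "local_fdr": fdr, "called": called.astype(int)}
        )


def call_associations(
    chain: ChainArchive, tau: float = 0.1, pairs="declared", summaries=None
) -> AssociationCalls:
    """Run FDR control for every phenotype and the requested pairs.

    ``pairs`` is "declared" (pairs of the called graph; needs ``summaries``
    or computes them), "all", "none", or an explicit list of pairs.
    """
    calls = AssociationCalls(tau=tau, snp_ids=list(chain.snp_ids))
    for name in chain.phenotypes:
        f = local_fdr(chain, phenotype=name)
        called, kappa = control_fdr(f, tau)
        realized = float(f[called].mean()) if called.any() else 0.0
        assert realized <= tau + 1e-12
        calls.per_phenotype[name] = (f, called, kappa)
    if pairs == "none":
        wanted = []
    elif pairs == "all":
        wanted = chain.pairs
    elif pairs == "declared":
        if summaries is None:
            summaries = summarize_edges(chain)
            declare_edges(summaries)
        wanted = [(s.i, s.j) for s in summaries if s.selected]
    else:
        wanted = [tuple(sorted((_resolve(chain, a), _resolve(chain, b)))) for a, b in pairs]
    for i, j in wanted:
        f = local_fdr(chain, pair=(i, j))
        called, kappa = control_fdr(f, tau)
        calls.per_pair[(chain.phenotypes[i], chain.phenotypes[j])] = (f, called, kappa)
    return calls


def _batch_mean_se(x: np.ndarray) -> float:
    """Standard error of the mean of a correlated series via batch means."""
    m = len(x)
    n_batch = max(min(20, m // 10), 2)
    usable = (m // n_batch) * n_batch
    batches = x[:usable].reshape(n_batch, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batch))


def geweke_z(trace, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means."""
    x = np.asarray(trace, dtype=float)
    a = x[: max(int(first * len(x)), 2)]
    b = x[-max(int(last * len(x)), 2):]
    se = np.hypot(_batch_mean_se(a), _batch_mean_se(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


def chain_diagnostics(chain: ChainArchive) -> dict:
    """Acceptance rates, Geweke z on the log-posterior, edge-trace summaries."""
    report = {"acceptance": dict(chain.accept), "n_stored": chain.n_stored}
    if chain.n_stored < 100:
        logger.warning("chain has fewer than 100 stored draws; partial diagnostics")
        report["warning"] = "short chain: fewer than 100 stored draws"
    main_lp = chain.logpost[chain.n_burnin:]
    if len(main_lp) >= 20:
        report["geweke_z_logpost"] = geweke_z(main_lp)
    report["logpost_mean"] = float(main_lp.mean())
    report["edge_inclusion"] = {
        f"{chain.phenotypes[i]}--{chain.phenotypes[j]}": float(chain.edge[:, k].mean())
        for k, (i, j) in enumerate(chain.pairs)
    }
    return report


def edges_to_frame(summaries: list[EdgeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "i": s.name_i, "j": s.name_j,
                "post_edge_prob": s.post_edge_prob, "exceed_prob": s.exceed_prob,
                "beta_mean_marginal": s.beta_mean_marginal,
                "beta_mean_conditional": s.beta_mean_conditional,
                "beta_q025": s.beta_q025_marginal, "beta_q975": s.beta_q975_marginal,
                "selected": int(s.selected),
            }
            for s in summaries
        ]
    )


def graph_to_dot(graph: PhenotypeGraph, names: list[str]) -> str:
    """DOT rendering of a called phenotype graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    for i, j in graph.edges():
        g.add_edge(names[i], names[j])
    lines = ["graph phenotypes {"]
    for node in g.nodes:
        lines.append(f'  "{node}";')
    for a, b in g.edges:
        lines.append(f'  "{a}" -- "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
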