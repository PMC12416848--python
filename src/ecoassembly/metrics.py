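"""Network-structure diagnostics of assembled communities.

All metrics operate on the *unweighted pair graph*: one node per species,
one edge per interacting unordered pair, labelled with the pair's unique
interaction type. Degree ignores consumer/resource direction. Modularity
uses the resolution-1 partition score optimized by Louvain; the
``effective increase`` of a metric is its value minus the mean over
Erdős–Rényi graphs of the same size and connectance, i.e. the part of the
structure not expected by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable

import networkx as nx
import numpy as np

from .community import Community, InteractionMatrices, InvariantError

__all__ = [
    "undirected_pair_graph",
    "connectance",
    "degree_entropy",
    "modularity",
    "effective_increase",
    "type_proportions",
    "MetricReport",
    "community_report",
]

log = logging.getLogger(__name__)

LOUVAIN_RESTARTS = 5


def undirected_pair_graph(net: InteractionMatrices) -> nx.Graph:
    """Unweighted graph with one edge per interacting pair.

    Each edge carries a ``type`` attribute in ``{"competition",
    "consumer_resource", "mutualism"}``. A consumer-resource pair yields a
    single edge regardless of direction.
    """
    S = net.S
    G = nx.Graph()
    G.add_nodes_from(range(S))
    comp = np.triu(net.c > 0, k=1)
    mut = np.triu(net.m > 0, k=1)
    consdir = (net.pplus > 0) | (net.pminus > 0).T  # [i, j]: i consumes j
    cons = np.triu(consdir | consdir.T, k=1)
    if np.any((comp & mut) | (comp & cons) | (mut & cons)):
        raise InvariantError("pair with more than one interaction type")
    for mask, kind in ((comp, "competition"), (cons, "consumer_resource"), (mut, "mutualism")):
        for i, j in np.argwhere(mask):
            G.add_edge(int(i), int(j), type=kind)
    return G


def connectance(graph: nx.Graph) -> float:
    """Fraction of realized pairs among all ``S(S-1)/2`` possible ones."""
    S = graph.number_of_nodes()
    if S < 2:
        log.debug("connectance undefined for S=%d; returning 0", S)
        return 0.0
    return graph.number_of_edges() / (S * (S - 1) / 2)


def degree_entropy(graph: nx.Graph) -> float:
    """Shannon entropy (nats) of the empirical degree distribution."""
    if graph.number_of_nodes() == 0:
        raise ValueError("degree entropy undefined on an empty graph")
    degrees = np.array([d for _, d in graph.degree()])
    _, counts = np.unique(degrees, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def modularity_of_partition(graph: nx.Graph, partition, resolution: float = 1.0) -> float:
    """Partition score ``sum_c (L_c/m - resolution * (k_c/2m)^2)``."""
    return nx.community.modularity(graph, partition, resolution=resolution)


def modularity(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> float:
    """Maximized modularity, via seeded Louvain greedy optimization.

    Louvain is a stochastic heuristic; the best of ``LOUVAIN_RESTARTS``
    seeded restarts is reported to stabilize the estimate.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    best = -np.inf
    for k in range(LOUVAIN_RESTARTS):
        part = nx.community.louvain_communities(graph, resolution=resolution, seed=seed + k)
        best = max(best, modularity_of_partition(graph, part, resolution))
    return float(best)


def effective_increase(
    metric_fn: Callable[[nx.Graph], float],
    graph: nx.Graph,
    n_random: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """Metric value minus its mean over Erdős–Rényi ``G(S, p=C)`` baselines.

    Random draws on which the metric is undefined (e.g. modularity of an
    edgeless draw) are skipped and logged; if every draw is undefined an
    error is raised.
    """
    rng = np.random.default_rng(rng)
    S = graph.number_of_nodes()
    if S < 2:
        raise ValueError("effective increase requires at least 2 nodes")
    p = connectance(graph)
    baseline = []
    for _ in range(n_random):
        er = nx.gnp_random_graph(S, p, seed=int(rng.integers(2**31)))
        try:
            baseline.append(metric_fn(er))
        except ValueError:
            log.debug("metric undefined on an ER draw; skipped")
    if not baseline:
        raise ValueError("metric undefined on every random baseline draw")
    return float(metric_fn(graph) - np.mean(baseline))


def type_proportions(net: InteractionMatrices) -> tuple[float, float, float]:
    """Proportions (competition, consumer-resource, mutualism) of realized pairs.

    Returns ``(0, 0, 0)`` for an edgeless community.
    """
    n_comp = int(np.triu(net.c > 0, k=1).sum())
    consdir = (net.pplus > 0) | (net.pminus > 0).T
    n_cons = int(np.triu(consdir | consdir.T, k=1).sum())
    n_mut = int(np.triu(net.m > 0, k=1).sum())
    total = n_comp + n_cons + n_mut
    if total == 0:
        return (0.0, 0.0, 0.0)
    return (n_comp / total, n_cons / total, n_mut / total)


@dataclass
class MetricReport:
    """Per-community structural summary."""

    S: int
    C: float
    SC: float
    prop_comp: float
    prop_cons: float
    prop_mut: float
    mean_abundance: float
    degree_entropy: float | None = None
    modularity: float | None = None
    degree_entropy_increase: float | None = None
    modularity_increase: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def community_report(
    com: Community,
    random_baseline: int = 0,
    rng: np.random.Generator | None = None,
    louvain_seed: int = 0,
) -> MetricReport:
    """Full structural report for one community.

    ``random_baseline > 0`` additionally computes degree-entropy and
    modularity effective increases against that many Erdős–Rényi draws.
    """
    G = undirected_pair_graph(com.net)
    S = com.S
    C = connectance(G)
    pc, pp, pm = type_proportions(com.net)
    report = MetricReport(
        S=S,
        C=C,
        SC=S * C,
        prop_comp=pc,
        prop_cons=pp,
        prop_mut=pm,
        mean_abundance=float(com.x.sum() / S) if S else 0.0,
    )
    if S > 0:
        report.degree_entropy = degree_entropy(G)
    if G.number_of_edges() > 0:
        report.modularity = modularity(G, seed=louvain_seed)
    if random_baseline > 0 and S >= 2:
        rng = np.random.default_rng(rng)
        report.degree_entropy_increase = effective_increase(
            degree_entropy, G, n_random=random_baseline, rng=rng
        )
        if G.number_of_edges() > 0:
            report.modularity_increase = effective_increase(
                lambda g: modularity(g, seed=louvain_seed), G, n_random=random_baseline, rng=rng
            )
    return report
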