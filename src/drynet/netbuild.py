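"""Signed network construction, topology metrics and null-model baselines.

Edges connect taxon pairs whose correlation passes both the magnitude cutoff
(|r| >= r_min, 0.6 by default) and the FDR gate (q < q_max, 0.001 by
default); the edge sign records the correlation's direction.  Topology
metrics — average degree avgK = 2E/N, average clustering coefficient avgCC,
average path distance GD, and the positive:negative edge ratio — are
computed on the unsigned skeleton, matching how single per-network values
are conventionally reported.  Null ensembles either rewire the observed
graph preserving the degree sequence (default) or draw Erdos-Renyi G(N, E)
graphs with the same node and edge counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .association import AssociationMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignedNetwork:
    """Undirected graph of retained taxa; edges carry r, sign and q."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    ratio: float | None  # None when there are no negative edges
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float | None  # None when no connected pair exists
    modularity: float | None = None

    def as_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "positive": self.n_positive,
            "negative": self.n_negative,
            "pos_neg_ratio": None if self.ratio is None else round(self.ratio, 3),
            "avgK": round(self.avg_degree, 3),
            "avgCC": round(self.avg_clustering, 3),
            "GD": None if self.avg_path_distance is None
                 else round(self.avg_path_distance, 3),
            "modularity": None if self.modularity is None
                 else round(self.modularity, 3),
        }


@dataclass
class NullSummary:
    method: str
    n_replicates: int
    seed: int
    means: dict[str, float]
    sds: dict[str, float]


def build_network(assoc: AssociationMatrix, r_min: float = 0.6,
                  q_max: float = 0.001,
                  domains: dict[str, str] | None = None) -> SignedNetwork:
    """Threshold an association matrix into a signed co-occurrence network.

    An edge is kept when |r| >= r_min (inclusive) and q < q_max (strict).
    Taxa left without any edge are excluded from the node set.
    """
    if assoc.q is None:
        raise ValueError("association matrix has no q-values; run bh_fdr first")
    ids = assoc.taxon_ids
    d = len(ids)
    graph = nx.Graph()
    iu, ju = np.triu_indices(d, k=1)
    keep = (np.abs(assoc.r[iu, ju]) >= r_min) & (assoc.q[iu, ju] < q_max)
    for i, j in zip(iu[keep], ju[keep]):
        r = float(assoc.r[i, j])
        graph.add_edge(
            ids[i], ids[j], r=r,
            sign="positive" if r > 0 else "negative",
            q=float(assoc.q[i, j]),
        )
    if graph.number_of_edges() == 0:
        logger.warning("build_network: no edges pass |r| >= %g and q < %g",
                       r_min, q_max)
    if domains:
        for node in graph.nodes:
            graph.nodes[node]["domain"] = domains.get(node, "")
    return SignedNetwork(graph)


def _mean_path_distance(graph: nx.Graph) -> float | None:
    """Mean unweighted shortest-path length over connected unordered pairs."""
    total = 0
    n_pairs = 0
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        k = len(component)
        if k < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        n_pairs += k * (k - 1) // 2
    if n_pairs == 0:
        return None
    return total / (2 * n_pairs)  # each ordered pair counted twice


def topology_summary(net: SignedNetwork,
                     modularity: float | None = None) -> TopologySummary:
    """Node/edge accounting and the standard per-network topology metrics."""
    graph = net.graph
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("cannot summarise an empty network")
    e = graph.number_of_edges()
    e_pos = sum(1 for _, _, s in graph.edges(data="sign") if s == "positive")
    e_neg = e - e_pos
    ratio = e_pos / e_neg if e_neg else None
    if ratio is None and e:
        logger.info("topology_summary: no negative edges; ratio undefined")
    avg_k = 2 * e / n
    avg_cc = float(np.mean(list(nx.clustering(graph).values()))) if n else 0.0
    gd = _mean_path_distance(graph)
    return TopologySummary(n, e, e_pos, e_neg, ratio, avg_k, avg_cc, gd, modularity)


def _rewire(graph: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving double-edge-swap randomisation (10E attempts)."""
    rewired = nx.Graph()
    rewired.add_nodes_from(graph.nodes)
    rewired.add_edges_from(graph.edges)
    e = rewired.number_of_edges()
    if e < 2:
        return rewired
    nswap = 10 * e
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        nx.double_edge_swap(rewired, nswap=nswap, max_tries=100 * nswap,
                            seed=seed)
    except nx.NetworkXAlgorithmError:
        logger.warning("null_ensemble: swap budget exhausted before %d swaps", nswap)
    return rewired


def null_ensemble(net: SignedNetwork, n_reps: int = 100, method: str = "rewire",
                  seed: int = 0) -> NullSummary:
    """Topology metrics of randomised replicates of the observed network.

    ``rewire`` preserves the degree sequence exactly via double edge swaps and
    then reassigns the observed sign multiset to edges at random; ``er``
    draws a uniform random graph with the same node and edge counts.  Each
    replicate's avgCC, GD and fast-greedy modularity Q feed the summary.
    """
    from .keystones import fast_greedy_partition  # local import: avoid cycle

    if n_reps < 2:
        raise ValueError("need at least 2 null replicates")
    if method not in ("rewire", "er"):
        raise ValueError(f"unknown null method {method!r}; use 'rewire' or 'er'")
    graph = net.graph
    signs = [s for _, _, s in graph.edges(data="sign")]
    rng = np.random.default_rng(seed)
    metrics: dict[str, list[float]] = {"avgCC": [], "GD": [], "Q": []}
    for _ in range(n_reps):
        if method == "rewire":
            rep = _rewire(graph, rng)
        else:
            rep = nx.gnm_random_graph(graph.number_of_nodes(),
                                      graph.number_of_edges(),
                                      seed=int(rng.integers(0, 2**31 - 1)))
        assert rep.number_of_nodes() == graph.number_of_nodes()
        assert rep.number_of_edges() == graph.number_of_edges()
        perm = rng.permutation(len(signs))
        for (u, v), k in zip(rep.edges, perm):
            rep.edges[u, v]["sign"] = signs[k]
        metrics["avgCC"].append(float(np.mean(list(nx.clustering(rep).values()))))
        gd = _mean_path_distance(rep)
        metrics["GD"].append(math.nan if gd is None else gd)
        if rep.number_of_edges():
            metrics["Q"].append(fast_greedy_partition(SignedNetwork(rep)).Q)
        else:
            metrics["Q"].append(math.nan)
    means = {k: float(np.nanmean(v)) for k, v in metrics.items()}
    sds = {k: float(np.nanstd(v, ddof=1)) for k, v in metrics.items()}
    return NullSummary(method, n_reps, seed, means, sds)
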