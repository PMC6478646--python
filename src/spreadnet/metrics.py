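"""Graph statistics and seedable synthetic-network generators.

The statistics (degree, Watts–Strogatz local clustering, two-hop ego
networks and their density) are the structural covariates used by the
simulation studies.  The generators build small, fully controlled
stand-ins for the word networks those studies were designed around:

* :func:`make_two_hop_testbed` — a phonological-style two-hop
  neighborhood with an exact target degree and a prescribed target
  clustering coefficient;
* :func:`make_semantic_testbed` — an association-style semantic network
  with designated (target, related prime, unrelated prime) triples.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Network

__all__ = [
    "TwoHopNetwork",
    "SemanticTestbed",
    "degree",
    "local_clustering",
    "two_hop_subgraph",
    "two_hop_density",
    "gnp_random_network",
    "make_two_hop_testbed",
    "make_semantic_testbed",
]


@dataclass
class TwoHopNetwork:
    """A network together with a designated target and its hop shells.

    ``one_hop`` nodes are exactly the target's neighbors; ``two_hop``
    nodes are neighbors-of-neighbors that are not themselves adjacent to
    the target.
    """

    network: Network
    target: str
    one_hop: frozenset[str]
    two_hop: frozenset[str]


@dataclass
class SemanticTestbed:
    """A semantic network plus (target, related prime, unrelated prime) triples.

    Each related prime is adjacent to its target; each unrelated prime
    sits at strictly greater shortest-path distance from the target.
    """

    network: Network
    triples: list[tuple[str, str, str]]


def degree(network: Network, node: str) -> int:
    """Number of distinct neighbors (out-neighbors when directed)."""
    return network.degree(node)


def local_clustering(network: Network, node: str) -> float:
    """Watts–Strogatz local clustering coefficient C_i = 2|e_jk| / k_i(k_i - 1).

    Computed on the undirected simple projection.  Nodes of degree < 2
    have no possible neighbor–neighbor edge; C_i is defined as 0 there.
    """
    network.require_node(node)
    return float(nx.clustering(network.to_undirected_simple(), node))


def two_hop_subgraph(network: Network, node: str) -> TwoHopNetwork:
    """Induced subgraph on the target, its neighbors, and their neighbors."""
    network.require_node(node)
    g = network.to_undirected_simple()
    one_hop = set(g.neighbors(node))
    two_hop: set[str] = set()
    for nbr in one_hop:
        two_hop.update(g.neighbors(nbr))
    two_hop -= one_hop
    two_hop.discard(node)
    keep = {node} | one_hop | two_hop
    sub = Network(g.subgraph(keep).copy())
    return TwoHopNetwork(sub, node, frozenset(one_hop), frozenset(two_hop))


def two_hop_density(network: Network, node: str) -> float:
    """Edge density |E| / C(|V|, 2) of the node's two-hop subgraph."""
    sub = two_hop_subgraph(network, node).network
    return float(nx.density(sub.to_undirected_simple()))


def gnp_random_network(n: int, p: float, seed: int) -> Network:
    """Erdős–Rényi G(n, p) with nodes labeled "1" ... "n"."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=int(seed))
    return Network(nx.relabel_nodes(g, {i: str(i + 1) for i in range(n)}))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_two_hop_testbed(
    k: int, c_target: float, outer_per_neighbor: int, seed: int
) -> TwoHopNetwork:
    """Two-hop neighborhood with exact target degree and prescribed clustering.

    The target gets exactly ``k`` one-hop neighbors;
    ``round(c_target * k(k-1)/2)`` distinct neighbor–neighbor edges
    (round half up) are placed uniformly at random, so the achieved
    clustering equals the request up to that rounding; each one-hop
    neighbor is then attached to ``outer_per_neighbor`` fresh two-hop
    nodes of its own.
    """
    if k < 2:
        raise ValueError(f"target degree k must be >= 2, got {k}")
    if not 0.0 <= c_target <= 1.0:
        raise ValueError(f"c_target must be in [0, 1], got {c_target}")
    if outer_per_neighbor < 0:
        raise ValueError("outer_per_neighbor must be >= 0")
    max_pairs = k * (k - 1) // 2
    n_edges = _round_half_up(c_target * max_pairs)
    if n_edges > max_pairs:
        raise ValueError(
            f"requested {n_edges} neighbor edges but only {max_pairs} are possible"
        )
    rng = np.random.default_rng(int(seed))
    g = nx.Graph()
    target = "t"
    neighbors = [f"n{i + 1}" for i in range(k)]
    g.add_node(target)
    for nb in neighbors:
        g.add_edge(target, nb)
    pairs = [(neighbors[i], neighbors[j]) for i in range(k) for j in range(i + 1, k)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    for idx in chosen:
        g.add_edge(*pairs[idx])
    for i, nb in enumerate(neighbors):
        for j in range(outer_per_neighbor):
            g.add_edge(nb, f"n{i + 1}_o{j + 1}")
    two_hop = frozenset(
        f"n{i + 1}_o{j + 1}" for i in range(k) for j in range(outer_per_neighbor)
    )
    return TwoHopNetwork(Network(g), target, frozenset(neighbors), two_hop)


def make_semantic_testbed(
    n_words: int,
    n_pairs: int,
    attachment: int = 2,
    seed: int = 0,
    min_unrelated_distance: int = 3,
) -> SemanticTestbed:
    """Association-style network with prime–target triples.

    A preferential-attachment (Barabási–Albert, ``attachment`` edges per
    new node) graph emulates the heavy-tailed degree distribution of
    free-association norms.  ``n_pairs`` disjoint triples are drawn:
    the related prime is a neighbor of its target, the unrelated prime a
    node at shortest-path distance >= ``min_unrelated_distance``.
    """
    if n_words < 3 * n_pairs:
        raise ValueError(
            f"n_words={n_words} cannot host {n_pairs} disjoint triples"
        )
    rng = np.random.default_rng(int(seed))
    g = nx.barabasi_albert_graph(n_words, attachment, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"w{i + 1}" for i in range(n_words)})
    net = Network(g)
    undirected = net.to_undirected_simple()

    used: set[str] = set()
    triples: list[tuple[str, str, str]] = []
    candidates = list(net.nodes)
    rng.shuffle(candidates)
    for target in candidates:
        if len(triples) == n_pairs:
            break
        if target in used:
            continue
        nbrs = [v for v in undirected.neighbors(target) if v not in used]
        if not nbrs:
            continue
        dist = nx.single_source_shortest_path_length(undirected, target)
        far = [
            v
            for v, d in dist.items()
            if d >= min_unrelated_distance and v not in used
        ]
        if not far:
            continue
        related = nbrs[rng.integers(len(nbrs))]
        unrelated = far[rng.integers(len(far))]
        triples.append((target, related, unrelated))
        used.update((target, related, unrelated))
    if len(triples) < n_pairs:
        raise ValueError(
            f"could only place {len(triples)} of {n_pairs} triples with the "
            f"distance->{min_unrelated_distance} constraint; increase n_words "
            "or lower attachment"
        )
    return SemanticTestbed(net, triples)
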