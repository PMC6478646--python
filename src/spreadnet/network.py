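"""Labeled simple-graph container used throughout the package.

A :class:`Network` wraps a :mod:`networkx` graph and enforces the
normalization contract assumed by the spreading-activation engine:
string labels, no self-loops, no parallel edges (their weights are
summed when the network is weighted), and strictly positive weights.
Unweighted networks behave identically to all-weights-equal-one.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

__all__ = ["Network", "normalize_graph"]


def normalize_graph(
    graph: nx.Graph | nx.DiGraph | nx.MultiGraph | nx.MultiDiGraph,
    *,
    weighted: bool = False,
) -> nx.Graph | nx.DiGraph:
    """Return a simple graph: self-loops dropped, parallel edges collapsed.

    Parallel edge weights are summed when ``weighted`` is set; otherwise
    every surviving edge carries weight 1.  Node labels are coerced to
    ``str``.
    """
    directed = graph.is_directed()
    out: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    for node in graph.nodes:
        out.add_node(str(node))
    edge_iter = graph.edges(data=True)
    for u, v, data in edge_iter:
        su, sv = str(u), str(v)
        if su == sv:
            continue
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        if w <= 0:
            raise ValueError(f"edge ({su}, {sv}) has non-positive weight {w}")
        if out.has_edge(su, sv):
            if weighted:
                out[su][sv]["weight"] += w
        else:
            out.add_edge(su, sv, weight=w)
    return out


class Network:
    """A labeled simple graph (optionally directed and/or weighted).

    Parameters
    ----------
    graph:
        Any networkx graph; it is normalized on construction (see
        :func:`normalize_graph`).
    weighted:
        When true, edge ``weight`` attributes are honored; otherwise all
        edges count as weight 1.
    """

    def __init__(self, graph: nx.Graph | nx.DiGraph, *, weighted: bool = False):
        self.graph = normalize_graph(graph, weighted=weighted)
        self.weighted = bool(weighted)
        self.directed = self.graph.is_directed()
        # stable node order: insertion order of the normalized graph
        self.nodes: tuple[str, ...] = tuple(self.graph.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("node labels are not unique after str() coercion")
        self._shares: dict[str, list[tuple[str, float]]] | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        *,
        nodes: Iterable[str] | None = None,
        directed: bool = False,
        weighted: bool = False,
    ) -> "Network":
        """Build from (u, v) or (u, v, weight) tuples."""
        g: nx.Graph | nx.DiGraph = nx.MultiDiGraph() if directed else nx.MultiGraph()
        if nodes is not None:
            g.add_nodes_from(str(n) for n in nodes)
        for edge in edges:
            if len(edge) == 2:
                g.add_edge(str(edge[0]), str(edge[1]), weight=1.0)
            else:
                g.add_edge(str(edge[0]), str(edge[1]), weight=float(edge[2]))
        return cls(g, weighted=weighted)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def require_node(self, label: str) -> None:
        if label not in self.index:
            raise KeyError(f"unknown node label: {label!r}")

    def neighbors(self, label: str) -> list[str]:
        """Out-neighbors for directed graphs, neighbors otherwise."""
        self.require_node(label)
        return list(self.graph.successors(label)) if self.directed else list(
            self.graph.neighbors(label)
        )

    def degree(self, label: str) -> int:
        """Number of distinct (out-)neighbors."""
        return len(self.neighbors(label))

    # -- spreading support -------------------------------------------------
    def outflow_shares(self) -> dict[str, list[tuple[str, float]]]:
        """Per-node outflow distribution: label -> [(neighbor, share)].

        Shares are weight-proportional (w_mj / sum_k w_mk) and sum to 1 for
        every node with at least one (out-)neighbor; nodes without
        out-neighbors map to an empty list and retain all activation.
        """
        if self._shares is None:
            shares: dict[str, list[tuple[str, float]]] = {}
            for node in self.nodes:
                nbrs = self.neighbors(node)
                if not nbrs:
                    shares[node] = []
                    continue
                if self.weighted:
                    ws = [self.graph[node][v]["weight"] for v in nbrs]
                    tot = sum(ws)
                    shares[node] = [(v, w / tot) for v, w in zip(nbrs, ws)]
                else:
                    share = 1.0 / len(nbrs)
                    shares[node] = [(v, share) for v in nbrs]
            self._shares = shares
        return self._shares

    def to_undirected_simple(self) -> nx.Graph:
        """Undirected, unweighted simple projection (for clustering etc.)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((u, v) for u, v in self.graph.edges())
        return g

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "directed" if self.directed else "undirected"
        wt = "weighted" if self.weighted else "unweighted"
        return f"<Network {kind} {wt} |V|={self.n_nodes} |E|={self.n_edges}>"
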