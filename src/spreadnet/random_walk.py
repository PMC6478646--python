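"""Random-walk comparator for the spreading-activation dynamics.

On a connected undirected graph the simple random walk's stationary
distribution is degree-proportional, pi(n) = deg(n) / 2|E| — the same
limit the conservative (no decay, no suppression) spreading process
converges to when normalized.  This module provides the transition
matrix, Monte-Carlo walk simulation, the closed-form stationary
distribution, and a direct comparison of long-run spreading activation
against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimParams, simulate, state_at
from .network import Network

__all__ = [
    "WalkSummary",
    "transition_matrix",
    "simulate_walks",
    "stationary_distribution",
    "compare_with_spreading",
    "SpreadingWalkComparison",
]


@dataclass
class WalkSummary:
    """Monte-Carlo summary of an ensemble of random walks.

    ``visited_fraction`` is the fraction of walks that touched each node
    at least once (not a distribution); ``visitation_prob`` is that
    vector normalized to sum to 1; ``endpoint_prob`` is the empirical
    distribution of final positions.
    """

    nodes: tuple[str, ...]
    visited_fraction: np.ndarray
    visitation_prob: np.ndarray
    endpoint_prob: np.ndarray
    n_walks: int
    steps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "visitation_prob": self.visitation_prob,
                "endpoint_prob": self.endpoint_prob,
            }
        )


def transition_matrix(network: Network) -> np.ndarray:
    """Row-stochastic transition matrix P[i, j] = prob of stepping i -> j.

    Unweighted undirected graphs get the standard 1/degree rule;
    weighted/directed graphs use out-weight-proportional shares.
    Isolated nodes (no out-neighbors) self-loop with probability 1 so
    every row sums to 1.
    """
    n = network.n_nodes
    p = np.zeros((n, n))
    shares = network.outflow_shares()
    for i, node in enumerate(network.nodes):
        out = shares[node]
        if not out:
            p[i, i] = 1.0
            continue
        for nbr, share in out:
            p[i, network.index[nbr]] += share
    return p


def simulate_walks(
    network: Network, start: str, steps: int, n_walks: int, seed: int
) -> WalkSummary:
    """Run ``n_walks`` independent random walks of ``steps`` steps from ``start``.

    Visitation counts each node at most once per walk; the endpoint
    distribution is the empirical law of the final position, which
    converges to the ``steps``-step row of the transition-matrix power
    at the Monte-Carlo O(1/sqrt(n_walks)) rate.
    """
    network.require_node(start)
    if steps < 1 or n_walks < 1:
        raise ValueError("steps and n_walks must both be >= 1")
    p = transition_matrix(network)
    cdf = np.cumsum(p, axis=1)
    rng = np.random.default_rng(int(seed))
    n = network.n_nodes
    pos = np.full(n_walks, network.index[start], dtype=np.int64)
    visited = np.zeros((n_walks, n), dtype=bool)
    visited[:, network.index[start]] = True
    walks = np.arange(n_walks)
    for _ in range(steps):
        u = rng.random(n_walks)
        pos = (cdf[pos] < u[:, None]).sum(axis=1)
        visited[walks, pos] = True
    visited_fraction = visited.mean(axis=0)
    endpoint = np.bincount(pos, minlength=n) / n_walks
    return WalkSummary(
        nodes=network.nodes,
        visited_fraction=visited_fraction,
        visitation_prob=visited_fraction / visited_fraction.sum(),
        endpoint_prob=endpoint,
        n_walks=n_walks,
        steps=steps,
        seed=int(seed),
    )


def stationary_distribution(network: Network) -> pd.Series:
    """Closed-form stationary law deg(n) / 2|E| of the simple walk.

    Requires a connected undirected network; on disconnected input the
    walk has no unique stationary law and the call is rejected with the
    component breakdown.
    """
    if network.directed:
        raise ValueError("stationary_distribution requires an undirected network")
    g = network.to_undirected_simple()
    if network.n_nodes and not nx.is_connected(g):
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValueError(
            f"network is disconnected (component sizes: {comps}); "
            "the stationary distribution is not unique"
        )
    two_m = 2 * network.n_edges
    if two_m == 0:
        raise ValueError("network has no edges")
    return pd.Series(
        {n: network.degree(n) / two_m for n in network.nodes}, name="stationary"
    )


@dataclass
class SpreadingWalkComparison:
    """Long-run spreading activation vs. the walk's stationary law."""

    l1_distance: float
    rank_correlation: float
    spreading: pd.Series
    stationary: pd.Series


def compare_with_spreading(
    network: Network,
    init: list[tuple[str, float]],
    retention: float,
    t_long: int,
) -> SpreadingWalkComparison:
    """Run conservative spreading for ``t_long`` steps and compare.

    The activation vector at ``t_long`` is normalized to a distribution
    and set against deg/2|E|; reports the L1 distance and the Spearman
    rank correlation along with both vectors.  With retention in (0, 1)
    the dynamics are a lazy walk, so convergence holds on bipartite
    graphs too.
    """
    if not 0.0 < retention < 1.0:
        raise ValueError("retention must lie strictly inside (0, 1)")
    pi = stationary_distribution(network)
    params = SimParams(retention=retention, decay=0.0, suppress=0.0, time_steps=t_long)
    history = simulate(network, init, params)
    final = state_at(history, t_long)
    total = final.total()
    if total <= 0:
        raise ValueError("no activation left to normalize")
    spreading = pd.Series(
        {n: final.activation[n] / total for n in network.nodes}, name="spreading"
    )
    l1 = float(np.abs(spreading.to_numpy() - pi.to_numpy()).sum())
    if np.ptp(pi.to_numpy()) < 1e-12:
        # regular graph: the stationary law is uniform and every ordering
        # is trivially consistent with it
        rho = 1.0
    else:
        rho = stats.spearmanr(spreading.to_numpy(), pi.to_numpy()).statistic
    return SpreadingWalkComparison(
        l1_distance=l1,
        rank_correlation=float(rho),
        spreading=spreading,
        stationary=pi,
    )
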