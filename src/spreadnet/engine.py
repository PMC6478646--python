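"""Time-stepped spreading-activation dynamics.

Each step, every node keeps a proportion ``r`` (retention) of its current
activation and spreads the remaining ``1 - r`` equally (or
weight-proportionally) to its neighbors.  After inflow aggregation the
whole network loses a proportion ``d`` (decay), and any node whose
activation has fallen strictly below the suppression threshold ``s`` is
zeroed.  With ``d = s = 0`` total activation is conserved exactly, so the
dynamics form a linear, mass-preserving diffusion on the graph — a lazy
random walk read as a deterministic flow.

The step itself (:func:`spread_step`) is a per-node loop over explicit
outflow shares.  :func:`transition_operator` provides the equivalent
matrix form (valid in the ``d = s = 0`` regime), which the test-suite uses
as an independent oracle via matrix powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "SimParams",
    "ActivationState",
    "materialize_initial",
    "spread_step",
    "simulate",
    "transition_operator",
    "total_activation",
    "state_at",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    retention:
        Proportion of activation a node keeps each step, in [0, 1].
    decay:
        Proportion of activation destroyed network-wide each step, in [0, 1].
    suppress:
        Activation floor: values strictly below it are zeroed at the end
        of a step (a value exactly equal survives).  Must be >= 0.
    time_steps:
        Number of steps T >= 1; the output history covers t = 0 ... T.
    """

    retention: float
    decay: float = 0.0
    suppress: float = 0.0
    time_steps: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"retention must be in [0, 1], got {self.retention}")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError(f"decay must be in [0, 1], got {self.decay}")
        if self.suppress < 0.0:
            raise ValueError(f"suppress must be >= 0, got {self.suppress}")
        if int(self.time_steps) != self.time_steps or self.time_steps < 1:
            raise ValueError(f"time_steps must be an integer >= 1, got {self.time_steps}")


@dataclass
class ActivationState:
    """Per-node activation at a single time index."""

    time: int
    activation: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.activation.values()))

    def copy(self) -> "ActivationState":
        return ActivationState(self.time, dict(self.activation))


def materialize_initial(
    network: Network, init: list[tuple[str, float]]
) -> ActivationState:
    """Expand an (node, activation) list to a full t=0 state.

    Named nodes carry their assigned (strictly positive) activation;
    every other node carries exactly 0.
    """
    seen: set[str] = set()
    activation = {n: 0.0 for n in network.nodes}
    for label, value in init:
        label = str(label)
        if label not in network.index:
            raise KeyError(f"initial activation names unknown node: {label!r}")
        if label in seen:
            raise ValueError(f"duplicate node in initial activation: {label!r}")
        value = float(value)
        if value <= 0.0:
            raise ValueError(
                f"initial activation must be > 0, got {value} for node {label!r}"
            )
        seen.add(label)
        activation[label] = value
    return ActivationState(0, activation)


def spread_step(
    state: ActivationState, network: Network, params: SimParams
) -> ActivationState:
    """One step of retention/spread, then decay, then suppression.

    Nodes without (out-)neighbors keep all their activation regardless of
    retention: the outflow share is undefined at degree zero.
    """
    r = params.retention
    shares = network.outflow_shares()
    nxt = {n: 0.0 for n in network.nodes}
    for node in network.nodes:
        a = state.activation[node]
        if a == 0.0:
            continue
        out = shares[node]
        if not out:
            nxt[node] += a
            continue
        nxt[node] += r * a
        spread = (1.0 - r) * a
        for nbr, share in out:
            nxt[nbr] += spread * share
    keep = 1.0 - params.decay
    s = params.suppress
    for node, value in nxt.items():
        value *= keep
        nxt[node] = 0.0 if value < s else value
    return ActivationState(state.time + 1, nxt)


def simulate(
    network: Network, init: list[tuple[str, float]], params: SimParams
) -> pd.DataFrame:
    """Run the dynamics for ``params.time_steps`` steps.

    Returns the activation history as a long table with columns
    ``node``, ``activation``, ``time`` covering t = 0 ... T
    ((T+1) x |V| rows); the t=0 slice is the materialized initial state.
    """
    state = materialize_initial(network, init)
    frames = [state]
    for _ in range(params.time_steps):
        state = spread_step(state, network, params)
        frames.append(state)
    records = [
        (node, st.activation[node], st.time)
        for st in frames
        for node in network.nodes
    ]
    return pd.DataFrame(records, columns=["node", "activation", "time"])


def transition_operator(network: Network, retention: float) -> np.ndarray:
    """Matrix form of one step in the no-decay, no-suppression regime.

    ``M[i, j] = r * [i == j] + (1 - r) * share(j -> i)`` over the node
    order of ``network.nodes``; applying ``M`` to an activation vector
    equals :func:`spread_step` with ``decay = suppress = 0``.  Columns of
    nodes with out-neighbors sum to 1 (isolated nodes are columns of the
    identity).
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError(f"retention must be in [0, 1], got {retention}")
    n = network.n_nodes
    m = np.zeros((n, n))
    shares = network.outflow_shares()
    for j, node in enumerate(network.nodes):
        out = shares[node]
        if not out:
            m[j, j] = 1.0
            continue
        m[j, j] = retention
        for nbr, share in out:
            m[network.index[nbr], j] += (1.0 - retention) * share
    return m


def total_activation(state: ActivationState) -> float:
    """Sum of activation over all nodes."""
    return state.total()


def state_at(history: pd.DataFrame, t: int) -> ActivationState:
    """Slice an activation history at time ``t`` back into a state."""
    rows = history[history["time"] == t]
    if rows.empty:
        raise KeyError(f"history has no rows at time {t}")
    return ActivationState(int(t), dict(zip(rows["node"], rows["activation"])))
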