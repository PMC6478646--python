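"""Readers and writers for networks and activation tables.

Supported network dialects: edge-list CSV/TSV (optional weight column),
square adjacency-matrix CSV (optional label header row/column), Pajek
``.net`` (*Vertices / *Edges / *Arcs), and GraphML.  All readers
normalize to a simple graph — self-loops removed, duplicate edges
collapsed — and reject malformed input naming the offending line or
field rather than coercing it.

Activation tables are CSV: initial activations with header
``node,activation`` and histories with header ``node,activation,time``
(rows ordered by time then node label; floats round-trip exactly).
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import Network

__all__ = [
    "read_network",
    "write_network",
    "read_initial",
    "write_history",
    "read_history",
]

_EDGE_HEADER_TOKENS = {
    "from", "to", "source", "target", "node1", "node2", "u", "v", "weight", "w",
}
_FORMATS = ("edgelist", "adjacency", "pajek", "graphml")

_EXT_TO_FORMAT = {
    ".csv": "edgelist",
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".net": "pajek",
    ".paj": "pajek",
    ".graphml": "graphml",
    ".xml": "graphml",
}


def _detect_format(path: Path) -> str:
    fmt = _EXT_TO_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer network format from {path.name!r}; "
            f"pass format explicitly (one of {_FORMATS})"
        )
    return fmt


def read_network(
    path: str | Path,
    format: str | None = None,
    directed: bool = False,
    weighted: bool = False,
    create_names: bool = True,
) -> Network:
    """Read a network file and normalize it to a simple graph.

    ``format`` is one of ``edgelist``, ``adjacency``, ``pajek``,
    ``graphml``; when omitted it is inferred from the file extension
    (except ``adjacency``, which shares .csv with edge lists and must be
    named).  ``create_names`` auto-labels unlabeled nodes "1"..."N" in
    input order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    fmt = format or _detect_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return _read_edgelist(path, directed, weighted)
    if fmt == "adjacency":
        return _read_adjacency(path, directed, weighted, create_names)
    if fmt == "pajek":
        return _read_pajek(path, directed, weighted)
    return _read_graphml(path, directed, weighted)


def _read_edgelist(path: Path, directed: bool, weighted: bool) -> Network:
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    edges = []
    for lineno, row in enumerate(csv.reader(_io.StringIO(text), delimiter=delimiter), 1):
        row = [c.strip() for c in row if c.strip() != ""]
        if not row:
            continue
        if lineno == 1 and all(c.lower() in _EDGE_HEADER_TOKENS for c in row):
            continue  # header row
        if len(row) == 2:
            edges.append((row[0], row[1]))
        elif len(row) == 3:
            try:
                w = float(row[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric weight {row[2]!r}"
                ) from exc
            edges.append((row[0], row[1], w))
        else:
            raise ValueError(
                f"{path.name}:{lineno}: expected 2 or 3 fields, got {len(row)}"
            )
    return Network.from_edges(edges, directed=directed, weighted=weighted)


def _read_adjacency(
    path: Path, directed: bool, weighted: bool, create_names: bool
) -> Network:
    df = pd.read_csv(path, header=None)
    # label header row: first cell empty or non-numeric first row
    first_row_numeric = pd.to_numeric(df.iloc[0], errors="coerce").notna().all()
    if not first_row_numeric:
        header = [str(x) for x in df.iloc[0]]
        body = df.iloc[1:]
        first_col_numeric = (
            pd.to_numeric(body.iloc[:, 0], errors="coerce").notna().all()
        )
        if first_col_numeric:
            labels = header
        else:
            labels = header[1:]
            body = body.iloc[:, 1:]
    else:
        body = df
        if create_names:
            labels = [str(i + 1) for i in range(df.shape[1])]
        else:
            raise ValueError(
                f"{path.name}: adjacency matrix has no labels and "
                "create_names is disabled"
            )
    try:
        mat = body.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric adjacency entry: {exc}") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"{path.name}: adjacency matrix is not square ({mat.shape[0]}x{mat.shape[1]})"
        )
    if len(labels) != mat.shape[1]:
        raise ValueError(f"{path.name}: label count does not match matrix size")
    if not directed and not (mat == mat.T).all():
        raise ValueError(
            f"{path.name}: adjacency matrix is asymmetric; pass directed=True"
        )
    edges = []
    n = mat.shape[0]
    for i in range(n):
        cols = range(n) if directed else range(i, n)
        for j in cols:
            if mat[i, j] != 0:
                edges.append((labels[i], labels[j], float(mat[i, j])))
    return Network.from_edges(
        edges, nodes=labels, directed=directed, weighted=weighted
    )


def _read_pajek(path: Path, directed: bool, weighted: bool) -> Network:
    try:
        g = nx.read_pajek(path)
    except Exception as exc:
        raise ValueError(f"{path.name}: malformed Pajek file: {exc}") from exc
    # read_pajek returns a MultiDiGraph for *Arcs files, MultiGraph otherwise
    if not directed and g.is_directed():
        g = nx.MultiGraph(g)
    if directed and not g.is_directed():
        g = nx.MultiDiGraph(g)
    return Network(g, weighted=weighted)


def _read_graphml(path: Path, directed: bool, weighted: bool) -> Network:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise ValueError(f"{path.name}: malformed GraphML file: {exc}") from exc
    if not directed and g.is_directed():
        g = g.to_undirected()
    if directed and not g.is_directed():
        g = g.to_directed()
    return Network(g, weighted=weighted)


def write_network(network: Network, path: str | Path, format: str | None = None) -> None:
    """Write a network as an edge-list CSV or GraphML file."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "edgelist":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            for u, v, data in network.graph.edges(data=True):
                if network.weighted:
                    writer.writerow([u, v, repr(float(data.get("weight", 1.0)))])
                else:
                    writer.writerow([u, v])
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r} (edgelist or graphml)")


def read_initial(path: str | Path) -> list[tuple[str, float]]:
    """Read an initial-activation CSV with header ``node,activation``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    required = ["node", "activation"]
    if list(df.columns[:2]) != required:
        raise ValueError(
            f"{path.name}: expected header 'node,activation', got {list(df.columns)}"
        )
    acts = pd.to_numeric(df["activation"], errors="coerce")
    if acts.isna().any():
        bad = df.loc[acts.isna(), "node"].tolist()
        raise ValueError(f"{path.name}: non-numeric activation for nodes {bad}")
    return [(str(n), float(a)) for n, a in zip(df["node"], acts)]


def write_history(history: pd.DataFrame, path: str | Path) -> None:
    """Write an activation history as CSV (header node,activation,time).

    Rows are ordered by time, then node label; floats are serialized
    with ``repr`` so that re-reading reproduces the history exactly.
    """
    path = Path(path)
    ordered = history.sort_values(["time", "node"], kind="mergesort")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "activation", "time"])
        for node, act, t in ordered[["node", "activation", "time"]].itertuples(
            index=False
        ):
            writer.writerow([node, repr(float(act)), int(t)])


def read_history(path: str | Path) -> pd.DataFrame:
    """Read back a history CSV written by :func:`write_history`."""
    df = pd.read_csv(path, dtype={"node": str}, float_precision="round_trip")
    if list(df.columns) != ["node", "activation", "time"]:
        raise ValueError(
            f"{Path(path).name}: expected header 'node,activation,time', "
            f"got {list(df.columns)}"
        )
    df["activation"] = df["activation"].astype(float)
    df["time"] = df["time"].astype(int)
    return df
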