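"""Weighted protein-protein interaction network: loading, confidence
filtering, edge costs, and the column-stochastic transition matrix.

Edges carry STRING-style integer combined scores in [0, 1000]. The edge
cost used by the Steiner-tree stage is ``1 - score/1000``, so after the
default confidence filter (score >= 700) costs lie in [0, 0.3]. The random
walk stage uses the unweighted adjacency normalized column-wise.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)


class WeightedNetwork:
    """Undirected simple graph with integer confidence scores on edges."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- basic views ----------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, int]]:
        return [
            (min(u, v), max(u, v), d["score"])
            for u, v, d in self.graph.edges(data=True)
        ]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def score(self, u: str, v: str) -> int:
        return self.graph[u][v]["score"]

    def cost(self, u: str, v: str) -> float:
        return edge_cost(self.graph[u][v]["score"])

    def subnetwork(self, nodes) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.subgraph(nodes).copy())

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.edges(), columns=["protein1", "protein2", "combined_score"]).to_csv(
            path, sep="\t", index=False
        )


def _check_score(score: float) -> int:
    if not float(score).is_integer() or not (0 <= score <= 1000):
        raise FormatError(f"combined score must be an integer in [0, 1000], got {score!r}")
    return int(score)


def load_network(path: str | Path) -> WeightedNetwork:
    """Load a STRING-style edge list (node_a, node_b, combined_score).

    Whitespace- or tab-separated, optional header, gzip accepted. Duplicate
    rows collapse to the maximum score; self-loops are dropped (logged).
    """
    df = pd.read_csv(path, sep=r"\s+", comment=None, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (node_a node_b combined_score)")
    first = df.columns[2]
    try:  # headerless file: the "column names" are really the first data row
        float(first)
        df = pd.concat(
            [pd.DataFrame([list(df.columns)], columns=df.columns), df],
            ignore_index=True,
        )
    except ValueError:
        pass
    df.columns = list(df.columns[:2]) + ["score"] + list(df.columns[3:])
    g = nx.Graph()
    n_self = 0
    for a, b, s in df.iloc[:, [0, 1, 2]].itertuples(index=False):
        score = _check_score(float(s))
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    if n_self:
        logger.info("%s: dropped %d self-loop rows", path, n_self)
    return WeightedNetwork(g)


def filter_confidence(net: WeightedNetwork, min_score: int = 700) -> WeightedNetwork:
    """Drop edges below ``min_score``, isolated nodes, and restrict to the
    largest connected component (logged).

    The component restriction keeps the random-walk transition matrix free
    of dangling columns and the Steiner stage on one connected instance.
    """
    if not (0 <= min_score <= 1000):
        raise FormatError(f"min_score must lie in [0, 1000], got {min_score}")
    g = nx.Graph()
    g.add_edges_from(
        (u, v, d) for u, v, d in net.graph.edges(data=True) if d["score"] >= min_score
    )
    if g.number_of_nodes() == 0:
        logger.warning("confidence filter at %d removed every edge", min_score)
        return WeightedNetwork(g)
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    if len(components) > 1:
        logger.info(
            "confidence filter left %d components; keeping the largest (%d of %d nodes)",
            len(components), len(components[0]), g.number_of_nodes(),
        )
    return WeightedNetwork(g.subgraph(components[0]).copy())


def edge_cost(score: int) -> float:
    """Cost of an interaction: one minus the confidence score fraction."""
    if not (0 <= score <= 1000):
        raise FormatError(f"score must lie in [0, 1000], got {score}")
    return 1.0 - score / 1000.0


def transition_matrix(net: WeightedNetwork, weighted: bool = False) -> tuple[sp.csc_matrix, list[str]]:
    """Column-stochastic transition matrix over a lexicographic node order.

    By default columns normalize the *unweighted* adjacency (each neighbor
    of a degree-k node gets mass 1/k); ``weighted=True`` normalizes the
    confidence scores instead. The network must be nonempty and connected.
    """
    order = net.nodes
    if not order:
        raise ContractError("cannot build a transition matrix for an empty network")
    if not nx.is_connected(net.graph):
        raise ContractError("transition matrix requires a connected network")
    index = {g: i for i, g in enumerate(order)}
    rows, cols, vals = [], [], []
    for u, v, d in net.graph.edges(data=True):
        w = float(d["score"]) if weighted else 1.0
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        vals += [w, w]
    n = len(order)
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    colsum = np.asarray(a.sum(axis=0)).ravel()
    # a connected network has no dangling column except the single-node
    # graph, whose lone column becomes a self-transition
    dangling = colsum == 0
    if dangling.any():
        a = a + sp.diags(dangling.astype(float))
        colsum = np.asarray(a.sum(axis=0)).ravel()
    w = a @ sp.diags(1.0 / colsum)
    return sp.csc_matrix(w), order
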