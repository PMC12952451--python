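"""Prize-collecting Steiner tree (PCST) module detection.

Each patient induces a prize map over network genes — the number of rare
non-synonymous variants in a gene divided by the gene's length in bases —
and the PCST stage extracts the connected subnetwork (a tree ``F``) that
minimizes

    o(F) = beta * sum_{v not in F} p(v)  +  sum_{e in F} c(e)

i.e. the penalty for prizes left outside the tree plus the cost of the
edges used to connect what is kept. ``beta`` trades off prize coverage
against edge expenditure; at ``beta = 0`` the empty-ish single-node tree is
optimal, and as ``beta`` grows the tree absorbs more prized genes.

Small instances (up to :data:`EXACT_MAX_NODES` nodes) are solved exactly by
enumerating connected induced subgraphs with a minimum-spanning-tree cost
for each candidate node set. Larger instances use a multi-root
shortest-path-tree heuristic with strong pruning: a Dijkstra tree on edge
costs is grown from each high-prize root and dynamic programming prunes
every subtree that does not pay for the edge supporting it. Strong pruning
is optimal for the tree it is given, so the heuristic is exact whenever
some shortest-path tree contains an optimal solution.

A separate brute-force oracle (:func:`exact_pcst_oracle`) enumerates all
node subsets and is used only for cross-checking at toy scale.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError
from .network import WeightedNetwork, edge_cost
from .variants import VariantRecord

logger = logging.getLogger(__name__)

#: Instances at or below this size are solved by exact enumeration.
EXACT_MAX_NODES = 15

Edge = tuple[str, str]


def _norm_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class PrizeMap:
    """Nonnegative per-gene prizes for one patient; absent genes score 0."""

    patient_id: str
    prizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: p for g, p in self.prizes.items() if p < 0}
        if bad:
            raise DataError(f"negative prizes are not allowed: {bad}")

    def get(self, gene: str) -> float:
        return self.prizes.get(gene, 0.0)

    def total(self) -> float:
        return float(sum(self.prizes.values()))

    def restrict_to(self, nodes) -> "PrizeMap":
        """Intersect with a node set, logging dropped prized genes."""
        node_set = set(nodes)
        dropped = sorted(g for g in self.prizes if g not in node_set)
        if dropped:
            logger.info(
                "patient %s: %d prized gene(s) absent from the network, dropped: %s",
                self.patient_id, len(dropped), ", ".join(dropped[:10]),
            )
        return PrizeMap(
            self.patient_id,
            {g: p for g, p in self.prizes.items() if g in node_set},
        )


@dataclass
class PCSTSolution:
    """A tree (node set + edge set) with its objective value."""

    patient_id: str
    tree_nodes: frozenset[str]
    tree_edges: frozenset[Edge]
    objective: float
    beta: float


@dataclass
class ModuleAggregate:
    """Cohort-level aggregation of per-patient solution trees."""

    gene_counts: dict[str, int]
    union_nodes: frozenset[str]
    union_edges: frozenset[Edge]

    def frequent_genes(self) -> pd.DataFrame:
        rows = sorted(self.gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["gene", "n_patients"])


# ----------------------------------------------------------------------
# prizes
# ----------------------------------------------------------------------

def compute_prizes(
    variants: list[VariantRecord],
    gene_lengths: dict[str, int],
    patient_id: str | None = None,
) -> PrizeMap:
    """Prize of a gene = (# filtered variants in the gene) / gene length.

    ``variants`` must belong to a single patient (checked). Genes without a
    known length are skipped with a log message; a nonpositive length is a
    data error.
    """
    patients = {v.patient_id for v in variants}
    if patient_id is None:
        if len(patients) > 1:
            raise DataError(f"variants span several patients: {sorted(patients)}")
        patient_id = next(iter(patients)) if patients else "NA"
    elif patients - {patient_id}:
        raise DataError(
            f"variants for {sorted(patients - {patient_id})} passed to patient {patient_id}"
        )
    counts = Counter(v.gene for v in variants)
    prizes: dict[str, float] = {}
    for gene, n in counts.items():
        if gene not in gene_lengths:
            logger.info("patient %s: no length for gene %s, prize skipped", patient_id, gene)
            continue
        length = gene_lengths[gene]
        if length <= 0:
            raise DataError(f"nonpositive length {length} for gene {gene}")
        prizes[gene] = n / length
    return PrizeMap(patient_id, prizes)


def select_de_genes(
    de_table: pd.DataFrame, logfc_min: float = 2.0, fdr_max: float = 0.01
) -> set[str]:
    """Genes with logFC strictly above ``logfc_min`` and FDR strictly below
    ``fdr_max`` (both boundaries excluded)."""
    cols = {c.lower(): c for c in de_table.columns}
    try:
        gene_c, lfc_c, fdr_c = cols["gene"], cols["logfc"], cols["fdr"]
    except KeyError as exc:
        raise DataError(f"DE table needs gene/logFC/FDR columns, has {list(de_table.columns)}") from exc
    mask = (de_table[lfc_c] > logfc_min) & (de_table[fdr_c] < fdr_max)
    return set(de_table.loc[mask, gene_c])


def add_de_prizes(prizes: PrizeMap, de_genes: set[str], bonus: float) -> PrizeMap:
    """Add a fixed bonus prize to every differentially expressed gene."""
    if bonus < 0:
        raise ConfigurationError(f"DE bonus must be >= 0, got {bonus}")
    merged = dict(prizes.prizes)
    for g in de_genes:
        merged[g] = merged.get(g, 0.0) + bonus
    return PrizeMap(prizes.patient_id, merged)


def load_gene_lengths(path) -> dict[str, int]:
    """Read a two-column TSV (gene, length in bases)."""
    df = pd.read_csv(path, sep="\t")
    gene_col, len_col = df.columns[0], df.columns[1]
    return {g: int(l) for g, l in zip(df[gene_col], df[len_col])}


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

def objective_value(
    net: WeightedNetwork,
    nodes: frozenset[str] | set[str],
    edges: frozenset[Edge] | set[Edge],
    prizes: PrizeMap,
    beta: float,
) -> float:
    """Recompute the PCST objective from a node/edge set (independent of
    any solver bookkeeping)."""
    excluded = prizes.total() - sum(prizes.get(g) for g in nodes)
    cost = sum(net.cost(u, v) for u, v in edges)
    return beta * excluded + cost


def _validate_tree(net: WeightedNetwork, nodes: frozenset[str], edges: frozenset[Edge]) -> None:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if set(g.nodes) != set(nodes) or not nx.is_tree(g):
        raise ContractError("solution is not a tree")


# ----------------------------------------------------------------------
# exact solvers
# ----------------------------------------------------------------------

def _mst_cost_and_edges(net: WeightedNetwork, nodes: frozenset[str]) -> tuple[float, frozenset[Edge]] | None:
    sub = net.graph.subgraph(nodes)
    if sub.number_of_nodes() != len(nodes) or not nx.is_connected(sub):
        return None
    mst = nx.minimum_spanning_tree(
        nx.Graph(
            (u, v, {"weight": edge_cost(d["score"])}) for u, v, d in sub.edges(data=True)
        )
        if sub.number_of_edges()
        else sub
    )
    cost = sum(d["weight"] for _, _, d in mst.edges(data=True))
    return cost, frozenset(_norm_edge(u, v) for u, v in mst.edges())


def _better(cand: tuple[float, frozenset, frozenset], best: tuple[float, frozenset, frozenset] | None) -> bool:
    """Tie-break: lower objective, then fewer nodes, then lexicographic node tuple."""
    if best is None:
        return True
    obj_c, nodes_c, _ = cand
    obj_b, nodes_b, _ = best
    key_c = (obj_c, len(nodes_c), tuple(sorted(nodes_c)))
    key_b = (obj_b, len(nodes_b), tuple(sorted(nodes_b)))
    # strict objective comparison with a hair of slack for float MST sums
    if obj_c < obj_b - 1e-12:
        return True
    if obj_c > obj_b + 1e-12:
        return False
    return key_c[1:] < key_b[1:]


def exact_pcst_oracle(net: WeightedNetwork, prizes: PrizeMap, beta: float = 1.0) -> PCSTSolution:
    """Brute-force reference: enumerate every nonempty node subset, keep the
    connected ones, span each with its MST, and return the global minimum.

    Refuses instances above 12 nodes. Ties break toward the smaller node
    set, then the lexicographically smallest node tuple.
    """
    nodes = net.nodes
    if len(nodes) > 12:
        raise ContractError(f"oracle limited to <= 12 nodes, got {len(nodes)}")
    if beta < 0:
        raise ConfigurationError(f"beta must be >= 0, got {beta}")
    prizes = prizes.restrict_to(nodes)
    total = prizes.total()
    best: tuple[float, frozenset, frozenset] | None = None
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            node_set = frozenset(combo)
            res = _mst_cost_and_edges(net, node_set)
            if res is None:
                continue
            cost, edges = res
            obj = beta * (total - sum(prizes.get(g) for g in node_set)) + cost
            cand = (obj, node_set, edges)
            if _better(cand, best):
                best = cand
    assert best is not None  # every single node is a connected subset
    obj, node_set, edges = best
    return PCSTSolution(prizes.patient_id, node_set, edges, obj, beta)


def _connected_subsets(graph: nx.Graph):
    """Yield every connected node subset exactly once.

    Classic enumeration: for each anchor node (in sorted order) generate all
    connected sets whose smallest-ranked member is the anchor, by expanding
    a frontier restricted to higher-ranked nodes.
    """
    order = sorted(graph.nodes)
    rank = {v: i for i, v in enumerate(order)}

    def expand(current: frozenset, frontier: tuple, banned: frozenset):
        # invariant: frontier entries are unique, disjoint from current/banned
        yield current
        for i, v in enumerate(frontier):
            new_banned = banned | frozenset(frontier[:i])
            rest = frontier[i + 1 :]
            seen = set(rest)
            extra = tuple(
                w
                for w in sorted(graph[v])
                if rank[w] > rank[anchor]
                and w not in current
                and w != v
                and w not in new_banned
                and w not in seen
            )
            yield from expand(current | {v}, rest + extra, new_banned)

    for anchor in order:
        nbrs = tuple(w for w in sorted(graph[anchor]) if rank[w] > rank[anchor])
        yield from expand(frozenset({anchor}), nbrs, frozenset())


def _solve_exact(net: WeightedNetwork, prizes: PrizeMap, beta: float) -> PCSTSolution:
    """Exact solution by connected-subgraph enumeration (small instances)."""
    total = prizes.total()
    best: tuple[float, frozenset, frozenset] | None = None
    for node_set in _connected_subsets(net.graph):
        res = _mst_cost_and_edges(net, node_set)
        cost, edges = res  # connected by construction
        obj = beta * (total - sum(prizes.get(g) for g in node_set)) + cost
        cand = (obj, node_set, edges)
        if _better(cand, best):
            best = cand
    obj, node_set, edges = best
    return PCSTSolution(prizes.patient_id, node_set, edges, obj, beta)


# ----------------------------------------------------------------------
# heuristic solver
# ----------------------------------------------------------------------

def _dijkstra_tree(net: WeightedNetwork, root: str) -> dict[str, str]:
    """Shortest-path tree on edge costs; returns child -> parent map."""
    dist = {root: 0.0}
    parent: dict[str, str] = {}
    heap = [(0.0, root)]
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, attr in net.graph[u].items():
            nd = d + edge_cost(attr["score"])
            if v not in dist or nd < dist[v] - 1e-15 or (abs(nd - dist[v]) <= 1e-15 and u < parent.get(v, "￿")):
                if v not in done:
                    dist[v] = nd
                    parent[v] = u
                    heapq.heappush(heap, (nd, v))
    return parent


def _strong_prune(
    net: WeightedNetwork, parent: dict[str, str], root: str, prizes: PrizeMap, beta: float
) -> tuple[frozenset[str], frozenset[Edge]]:
    """Optimal pruning of a fixed tree: keep a child subtree only if its
    accumulated prize gain exceeds the cost of the edge supporting it."""
    children: dict[str, list[str]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    gain: dict[str, float] = {}
    keep_edge: dict[str, bool] = {}
    # post-order via iterative DFS
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if not processed:
            stack.append((node, True))
            for c in children.get(node, []):
                stack.append((c, False))
        else:
            g = beta * prizes.get(node)
            for c in children.get(node, []):
                net_gain = gain[c] - net.cost(node, c)
                keep_edge[c] = net_gain > 1e-15
                if keep_edge[c]:
                    g += net_gain
            gain[node] = g
    nodes = {root}
    edges: set[Edge] = set()
    queue = [root]
    while queue:
        u = queue.pop()
        for c in children.get(u, []):
            if keep_edge.get(c):
                nodes.add(c)
                edges.add(_norm_edge(u, c))
                queue.append(c)
    return frozenset(nodes), frozenset(edges)


def _solve_heuristic(
    net: WeightedNetwork, prizes: PrizeMap, beta: float, n_roots: int = 20
) -> PCSTSolution:
    total = prizes.total()
    prized = sorted(prizes.prizes, key=lambda g: (-prizes.get(g), g))
    roots = prized[:n_roots] or [net.nodes[0]]
    best: tuple[float, frozenset, frozenset] | None = None
    for root in roots:
        parent = _dijkstra_tree(net, root)
        nodes, edges = _strong_prune(net, parent, root, prizes, beta)
        obj = beta * (total - sum(prizes.get(g) for g in nodes)) + sum(
            net.cost(u, v) for u, v in edges
        )
        if _better((obj, nodes, edges), best):
            best = (obj, nodes, edges)
    # the best single node is always a candidate (covers beta == 0)
    single = min(net.nodes, key=lambda g: (-prizes.get(g), g))
    obj_single = beta * (total - prizes.get(single))
    if _better((obj_single, frozenset({single}), frozenset()), best):
        best = (obj_single, frozenset({single}), frozenset())
    obj, nodes, edges = best
    return PCSTSolution(prizes.patient_id, nodes, edges, obj, beta)


def solve_pcst(
    net: WeightedNetwork,
    prizes: PrizeMap,
    beta: float = 1.0,
    exact_max_nodes: int = EXACT_MAX_NODES,
) -> PCSTSolution:
    """Solve the PCST instance for one patient.

    Exact (connected-subgraph enumeration) up to ``exact_max_nodes`` nodes,
    heuristic (multi-root shortest-path trees with strong pruning) above.
    Deterministic: all tie-breaks are lexicographic. With an all-zero prize
    map the lexicographically first node is returned with objective 0.
    """
    if beta < 0:
        raise ConfigurationError(f"beta must be >= 0, got {beta}")
    if net.n_nodes == 0:
        raise ContractError("cannot solve PCST on an empty network")
    if not nx.is_connected(net.graph):
        raise ContractError("PCST stage requires a connected network")
    prizes = prizes.restrict_to(net.nodes)
    if prizes.total() == 0.0:
        logger.warning("patient %s: all prizes are zero; returning a single node", prizes.patient_id)
        first = net.nodes[0]
        return PCSTSolution(prizes.patient_id, frozenset({first}), frozenset(), 0.0, beta)
    if beta == 0.0:
        first = net.nodes[0]
        return PCSTSolution(prizes.patient_id, frozenset({first}), frozenset(), 0.0, beta)
    if net.n_nodes <= exact_max_nodes:
        sol = _solve_exact(net, prizes, beta)
    else:
        sol = _solve_heuristic(net, prizes, beta)
    _validate_tree(net, sol.tree_nodes, sol.tree_edges)
    return sol


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------

def aggregate_modules(solutions: list[PCSTSolution]) -> ModuleAggregate:
    """Per-gene patient frequencies and the union graph of all trees."""
    counts: Counter[str] = Counter()
    union_nodes: set[str] = set()
    union_edges: set[Edge] = set()
    for sol in solutions:
        counts.update(sol.tree_nodes)
        union_nodes |= sol.tree_nodes
        union_edges |= sol.tree_edges
    return ModuleAggregate(dict(counts), frozenset(union_nodes), frozenset(union_edges))
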