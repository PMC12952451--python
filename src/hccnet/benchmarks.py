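"""Seeded benchmark routines: solver-vs-oracle agreement and planted-truth
recovery on synthetic cohorts.

These run the real pipeline stages against their independent references
(subset-enumeration PCST oracle, direct linear solve for the random walk,
planted generator truth) and report summary rates. Both the test suite and
the reproduction script call them.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .network import WeightedNetwork, filter_confidence
from .pcst import PrizeMap, exact_pcst_oracle, objective_value, solve_pcst
from .resistance import carriers_per_group, count_matrix, fisher_exact_two_sided
from .rwr import RWRConfig, rwr, rwr_linear_solve
from .synth import (
    RESISTANT,
    SENSITIVE,
    SyntheticConfig,
    generate_cohort,
    generate_network,
    planted_prizes,
)
from .variants import Origin, filter_rare_nonsynonymous


def _random_connected(rng: np.random.Generator, n: int, p: float) -> WeightedNetwork:
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g[u][v]["score"] = int(rng.integers(700, 1001))
    return WeightedNetwork(g)


def pcst_oracle_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Solver objective vs subset-enumeration oracle on random instances
    of at most 10 nodes; also re-verifies every stored objective."""
    rng = np.random.default_rng([seed, 31])
    agree = 0
    max_recompute_gap = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 11))
        net = _random_connected(rng, n, 0.45)
        prizes = PrizeMap(
            "bench",
            {g: float(rng.uniform(0, 0.5)) for g in net.nodes if rng.random() < 0.7},
        )
        beta = float(rng.uniform(0.3, 2.0))
        sol = solve_pcst(net, prizes, beta)
        oracle = exact_pcst_oracle(net, prizes, beta)
        if abs(sol.objective - oracle.objective) <= 1e-9:
            agree += 1
        gap = abs(
            objective_value(net, sol.tree_nodes, sol.tree_edges, prizes.restrict_to(net.nodes), beta)
            - sol.objective
        )
        max_recompute_gap = max(max_recompute_gap, gap)
    return {
        "agreement_rate": agree / n_instances,
        "max_recompute_gap": max_recompute_gap,
        "n": n_instances,
    }


def rwr_linear_agreement(n_instances: int = 20, seed: int = 0) -> dict:
    """Power-iteration scores vs direct solve of (I - (1-gamma)W)p = gamma p0."""
    rng = np.random.default_rng([seed, 37])
    worst = 0.0
    worst_sum = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 51))
        net = _random_connected(rng, n, 0.25)
        nodes = net.nodes
        seeds = {nodes[i] for i in rng.choice(n, size=max(1, n // 10), replace=False)}
        it = rwr(net, seeds, RWRConfig())
        direct = rwr_linear_solve(net, seeds)
        worst = max(worst, max(abs(it.scores[g] - direct[g]) for g in direct))
        worst_sum = max(worst_sum, abs(sum(it.scores.values()) - 1.0))
    return {"max_abs_diff": worst, "max_sum_deviation": worst_sum, "n": n_instances}


def planted_module_recovery(n_replicates: int = 20, seed: int = 0, **cfg_kwargs) -> dict:
    """Fraction of synthetic replicates whose PCST tree contains the full
    planted high-prize module."""
    hits = 0
    for k in range(n_replicates):
        cfg = SyntheticConfig(seed=(seed * 1009 + k) % 2**31, **cfg_kwargs)
        edges, truth = generate_network(cfg)
        g = nx.Graph()
        for u, v, s in edges.itertuples(index=False):
            g.add_edge(u, v, score=s)
        net = filter_confidence(WeightedNetwork(g))
        prizes = planted_prizes(cfg, truth["module_genes"]).restrict_to(net.nodes)
        sol = solve_pcst(net, prizes, beta=1.0)
        if set(truth["module_genes"]) <= set(sol.tree_nodes):
            hits += 1
    return {"recovery_rate": hits / n_replicates, "n": n_replicates}


def _germline_panel_p(cfg: SyntheticConfig) -> float:
    """One synthetic replicate: rare germline carrier test on the panel."""
    cohort = generate_cohort(cfg)
    labels = {p: g for p, g in cohort.labels.items() if g in (SENSITIVE, RESISTANT)}
    filtered = [
        v for v in filter_rare_nonsynonymous(cohort.germline) if v.patient_id in labels
    ]
    matrix = count_matrix(filtered, cohort.panel, labels, Origin.GERMLINE)
    return fisher_exact_two_sided(carriers_per_group(matrix))


#: Planted "strong" enrichment: mean 4 qualifying germline panel variants
#: per resistant patient (carrier probability ~0.98).
STRONG_ENRICHMENT = 4.0


def germline_power(n_replicates: int = 50, seed: int = 0, enrichment: float = STRONG_ENRICHMENT) -> dict:
    """Rejection rate at alpha = 0.05 under planted resistant-only
    germline enrichment."""
    hits = 0
    for k in range(n_replicates):
        cfg = SyntheticConfig(seed=(seed * 1013 + k) % 2**31, enrichment_rate=enrichment)
        hits += _germline_panel_p(cfg) < 0.05
    return {"power": hits / n_replicates, "n": n_replicates}


def null_rejection_rate(n_replicates: int = 50, seed: int = 0) -> dict:
    """Rejection rate at alpha = 0.05 with zero enrichment (null
    calibration: both groups share the background mutation model)."""
    hits = 0
    for k in range(n_replicates):
        cfg = SyntheticConfig(seed=(seed * 1019 + k) % 2**31, enrichment_rate=0.0)
        hits += _germline_panel_p(cfg) < 0.05
    return {"rejection_rate": hits / n_replicates, "n": n_replicates}
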