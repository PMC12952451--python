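"""Shared fixtures and small graph/cohort builders."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from hccnet.network import WeightedNetwork
from hccnet.variants import Origin, VariantRecord, Zygosity


def make_network(edges: list[tuple[str, str, int]]) -> WeightedNetwork:
    g = nx.Graph()
    for u, v, s in edges:
        g.add_edge(u, v, score=s)
    return WeightedNetwork(g)


def random_connected_network(
    rng: np.random.Generator,
    n: int,
    p: float = 0.4,
    score_lo: int = 700,
    score_hi: int = 1000,
) -> WeightedNetwork:
    """Connected Erdos-Renyi graph with integer scores, node names N00..."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and (n == 1 or g.number_of_edges() > 0):
            break
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g[u][v]["score"] = int(rng.integers(score_lo, score_hi + 1))
    return WeightedNetwork(g)


def make_variant(
    patient="P1",
    gene="TP53",
    origin=Origin.SOMATIC,
    consequence="missense_variant",
    af=0.0001,
    zygosity=Zygosity.HET,
    variant_id="rs1",
    **kw,
) -> VariantRecord:
    return VariantRecord(
        patient_id=patient,
        gene=gene,
        origin=origin,
        consequence=consequence,
        gnomad_af=af,
        zygosity=zygosity,
        variant_id=variant_id,
        **kw,
    )


@pytest.fixture(scope="session")
def fixture_tables():
    from hccnet.synth import load_fixture_tables

    return load_fixture_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
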