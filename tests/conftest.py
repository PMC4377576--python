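import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from herbnet.core_io import CompoundRecord, InteractionNetwork, ReferenceDrug
from herbnet.synth import PRESETS, generate_bundle


def make_network(edges, nodes=()):
    net = InteractionNetwork()
    for n in nodes:
        net.add_node(n)
    for u, v in edges:
        net.add_edge(u, v, {"test"})
    return net


def random_network(rng, n_min=3, n_max=8):
    """Small random simple graph for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    net = InteractionNetwork()
    for node in g.nodes:
        net.add_node(node)
    for u, v in g.edges:
        net.add_edge(u, v, {"rand"})
    return net


@pytest.fixture
def path4():
    """The 4-node path A-B-C-D with a hand-checkable two-drug panel."""
    net = make_network([("A", "B"), ("B", "C"), ("C", "D")])
    d1 = ReferenceDrug("D1", frozenset({0, 1, 2}), 16, frozenset({"A"}))
    d2 = ReferenceDrug("D2", frozenset({8, 9, 10}), 16, frozenset({"D"}))
    query = CompoundRecord("q1", "herbX", frozenset({0, 1, 2}), 16)
    return net, [d1, d2], query


@pytest.fixture(scope="session")
def toy_bundle():
    import dataclasses

    return generate_bundle(dataclasses.replace(PRESETS["toy"], seed=7))
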