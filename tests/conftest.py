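import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

from mina import Interactome, SeedSet, find_connector_network


def build_net(edges, extra_nodes=()):
    """Interactome from (a, b, kind) or (a, b) tuples; kind defaults direct."""
    net = Interactome()
    for node in extra_nodes:
        net.add_node(node)
    for e in edges:
        a, b, *rest = e
        net.add_edge(a, b, rest[0] if rest else "direct")
    return net


def brute_force_objective(graph, seeds, max_nodes):
    """Exhaustive (seeds-in, -connectors) optimum over connected induced
    subgraphs within the node budget.  Independent oracle for the greedy
    search; only feasible on small graphs."""
    nodes = sorted(graph.nodes)
    best = (0, 0)
    for r in range(1, min(len(nodes), max_nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sg = graph.subgraph(subset)
            if not nx.is_connected(sg):
                continue
            k = len(set(subset) & set(seeds))
            obj = (k, -(r - k))
            if obj > best:
                best = obj
    return best


def search_quiet(net, seeds, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return find_connector_network(net, SeedSet(tuple(seeds)), **kw)


@pytest.fixture
def star_net():
    """Three seeds each adjacent only to one hub."""
    return build_net([("A", "H"), ("B", "H"), ("C", "H")])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
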