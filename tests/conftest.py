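import math

import networkx as nx
import numpy as np
import pytest

from wireconomy import (
    ChromosomeMap,
    CircularEmbedding,
    GeneRecord,
    RegulatoryInteraction,
    RegulatoryNetwork,
    build_trn,
)


@pytest.fixture
def small_chromosome() -> ChromosomeMap:
    """Six genes on a 10-kb circle; two multi-gene operons and two singletons.

    Layout (1-based): opA = {a1, a2} contiguous, opB = {b1, b2}, plus the
    unannotated genes reg1 and reg2 (auto-singleton operons).
    """
    genes = [
        GeneRecord("a1", 100, 600, "+", "opA"),
        GeneRecord("a2", 620, 1100, "+", "opA"),
        GeneRecord("b1", 4000, 4500, "-", "opB"),
        GeneRecord("b2", 4520, 5000, "-", "opB"),
        GeneRecord("reg1", 2500, 3000, "+"),
        GeneRecord("reg2", 7500, 8000, "-"),
    ]
    return ChromosomeMap(10_000, genes)


@pytest.fixture
def small_trn(small_chromosome) -> RegulatoryNetwork:
    interactions = [
        RegulatoryInteraction("reg1", "a1", "activation"),
        RegulatoryInteraction("reg1", "b1", "repression"),
        RegulatoryInteraction("reg1", "reg2", "activation"),
        RegulatoryInteraction("reg2", "b2", "activation"),
        RegulatoryInteraction("reg2", "a2", "repression"),
    ]
    return build_trn(interactions, level="gene", chromosome=small_chromosome)


def random_digraph(rng: np.random.Generator, n_nodes: int, n_edges: int):
    """Simple directed graph with string node ids (no self-loops)."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        u, v = rng.integers(0, n_nodes, size=2)
        attempts += 1
        if u != v:
            edges.add((nodes[u], nodes[v]))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return RegulatoryNetwork(g)


def random_embedding(rng: np.random.Generator, nodes) -> CircularEmbedding:
    nodes = list(nodes)
    return CircularEmbedding(
        dict(zip(nodes, rng.uniform(0, 2 * math.pi, size=len(nodes)))),
        genome_length_bp=1_000_000,
    )
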