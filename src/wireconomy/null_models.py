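"""Null models for spatially embedded regulatory networks.

Three randomizations of the (network, embedding) pair are provided:

* **edge swap** — degree-preserving switch randomization of the directed
  edges: a pair of edges (a->b, c->d) is replaced by (a->d, c->b) unless the
  move would create a self-loop, a parallel edge, or (optionally) an edge
  inside one operon.  In- and out-degrees are preserved exactly; node
  positions are untouched.
* **node swap** — repeated exchange of the positions of two randomly chosen
  nodes.  Topology and the multiset of positions are preserved; only the
  assignment of positions to nodes is randomized (gene density is thereby
  conserved).
* **random positions** — every node receives an i.i.d. uniform angle on the
  circle.  Topology is preserved, gene density is not.

For the coregulatory network two null constructions exist: swapping the CRN
edges directly (edge count preserved), or rebuilding the CRN from a
randomized TRN (edge count not preserved).  A chained "base model" variant
re-randomizes the previous replicate to check that the randomizer is
unbiased.  Ensembles carry full seed provenance: replicate k derives its
seed from the master seed via ``numpy.random.SeedSequence`` spawning, so
ensembles are reproducible and parallelizable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .embedding_metrics import (
    TWO_PI,
    CircularEmbedding,
    _angular_separation,
)
from .network_model import CoregulatoryNetwork, RegulatoryNetwork

__all__ = [
    "NULL_METHODS",
    "NullModelSpec",
    "NullEnsemble",
    "edge_swap_randomize",
    "node_swap_randomize",
    "random_positions",
    "crn_null",
    "base_model_chain",
    "generate_ensemble",
]

NULL_METHODS = (
    "edge_swap",
    "node_swap",
    "random_positions",
    "crn_edge_swap",
    "crn_from_randomized_trn",
)

#: metrics an ensemble can record per replicate
ENSEMBLE_METRICS = (
    "total_wiring_length",
    "total_genomic_distance",
    "processing_steps",
    "regulatory_span",
)


@dataclass(frozen=True)
class NullModelSpec:
    """Parameters of one null model.

    ``swap_intensity`` is attempted swaps per edge for the edge-swap methods
    (default 10) and swaps per node for node swap (default 100, the value
    used for the published analysis).  ``base_trn_method`` only matters for
    ``crn_from_randomized_trn``.
    """

    method: str
    seed: int = 0
    n_replicates: int = 1000
    swap_intensity: float | None = None
    forbid_self: bool = True
    forbid_within_operon: bool = True
    base_trn_method: str = "edge_swap"

    def __post_init__(self) -> None:
        if self.method not in NULL_METHODS:
            raise ValueError(
                f"unknown null-model method {self.method!r}; "
                f"choose from {NULL_METHODS}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.swap_intensity is not None and self.swap_intensity <= 0:
            raise ValueError("swap_intensity must be positive")

    @property
    def intensity(self) -> float:
        if self.swap_intensity is not None:
            return self.swap_intensity
        return 100.0 if self.method == "node_swap" else 10.0

    def replicate_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.n_replicates)


# ---------------------------------------------------------------------------
# low-level moves (integer- or id-coded edge lists; mutate in place)


def _swap_directed(edges: list, n_attempts: int, rng, operon_of=None) -> int:
    """Switch-randomize a directed edge list in place; returns accepted count.

    Rejected moves (self-loop, parallel edge, within-operon edge) are
    counted against the attempt budget, not retried.
    """
    m = len(edges)
    if m < 2 or n_attempts < 1:
        return 0
    edge_set = set(edges)
    pairs = rng.integers(0, m, size=(int(n_attempts), 2)).tolist()
    accepted = 0
    for i, j in pairs:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        if operon_of is not None and (
            operon_of[a] == operon_of[d] or operon_of[c] == operon_of[b]
        ):
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        accepted += 1
    return accepted


def _swap_undirected(edges: list, n_attempts: int, rng) -> int:
    """Degree-preserving swap on an undirected edge list (canonical tuples)."""
    m = len(edges)
    if m < 2 or n_attempts < 1:
        return 0

    def canon(u, v):
        return (u, v) if u <= v else (v, u)

    edge_set = set(edges)
    pairs = rng.integers(0, m, size=(int(n_attempts), 2)).tolist()
    flips = rng.integers(0, 2, size=int(n_attempts)).tolist()
    accepted = 0
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:  # randomize which endpoints pair up
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        e1, e2 = canon(a, d), canon(c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove(canon(a, b))
        edge_set.remove(canon(c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        accepted += 1
    return accepted


def _swap_values(values: list, n_ops: int, rng) -> None:
    """Apply n_ops random transpositions (distinct indices) in place."""
    n = len(values)
    if n < 2 or n_ops < 1:
        return
    first = rng.integers(0, n, size=int(n_ops)).tolist()
    second = rng.integers(0, n - 1, size=int(n_ops)).tolist()
    for i, j in zip(first, second):
        if j >= i:  # shift so that j != i, keeping j uniform on the rest
            j += 1
        values[i], values[j] = values[j], values[i]


def _operon_lookup(network: RegulatoryNetwork) -> dict | None:
    """Total node -> operon map (unannotated nodes count as singletons)."""
    if not network.operon_map:
        return None
    return {
        n: network.operon_map.get(n, n) for n in network.graph.nodes
    }


# ---------------------------------------------------------------------------
# public randomizers


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def edge_swap_randomize(
    network: RegulatoryNetwork,
    intensity: float = 10.0,
    seed: int | np.random.Generator | None = None,
    forbid_within_operon: bool = True,
) -> RegulatoryNetwork:
    """Degree-preserving switch randomization of a directed network.

    ``intensity`` is attempted swaps per edge.  With fewer than two edges the
    network is returned unchanged and flagged.  Swap provenance is stored in
    ``result.graph.graph`` under ``swap_attempted`` / ``swap_accepted``.
    """
    rng = _as_rng(seed)
    edges = list(network.graph.edges)
    g = nx.DiGraph()
    g.add_nodes_from(network.graph.nodes)
    if len(edges) < 2:
        g.add_edges_from(edges)
        g.graph["swap_warning"] = "fewer than 2 edges; returned unchanged"
        g.graph["swap_attempted"] = 0
        g.graph["swap_accepted"] = 0
        return RegulatoryNetwork(g, network.level, dict(network.operon_map))
    operon_of = _operon_lookup(network) if forbid_within_operon else None
    n_attempts = int(round(intensity * len(edges)))
    accepted = _swap_directed(edges, n_attempts, rng, operon_of)
    g.add_edges_from(edges)
    g.graph["swap_attempted"] = n_attempts
    g.graph["swap_accepted"] = accepted
    return RegulatoryNetwork(g, network.level, dict(network.operon_map))


def node_swap_randomize(
    embedding: CircularEmbedding,
    swaps_per_node: float = 100.0,
    seed: int | np.random.Generator | None = None,
) -> CircularEmbedding:
    """Randomize the node -> position assignment by repeated pair swaps.

    Performs ``round(swaps_per_node * N / 2)`` swap operations so that each
    node takes part in ``swaps_per_node`` swaps on average.  The multiset of
    angles is preserved exactly; the network is untouched by construction.
    """
    rng = _as_rng(seed)
    nodes = list(embedding.angles)
    if len(nodes) < 2:
        return CircularEmbedding(
            dict(embedding.angles), embedding.genome_length_bp
        )
    values = [embedding.angles[n] for n in nodes]
    n_ops = int(round(swaps_per_node * len(nodes) / 2.0))
    _swap_values(values, n_ops, rng)
    return CircularEmbedding(
        dict(zip(nodes, values)), embedding.genome_length_bp
    )


def random_positions(
    embedding: CircularEmbedding,
    seed: int | np.random.Generator | None = None,
) -> CircularEmbedding:
    """Assign every node an i.i.d. Uniform[0, 2*pi) angle.

    Randomizes distances most aggressively but does not preserve the (often
    highly nonuniform) gene density along the chromosome.
    """
    rng = _as_rng(seed)
    nodes = list(embedding.angles)
    angles = rng.uniform(0.0, TWO_PI, size=len(nodes))
    return CircularEmbedding(
        dict(zip(nodes, angles.tolist())), embedding.genome_length_bp
    )


def _crn_edges_from_trn_edges(edges: Iterable[tuple]) -> set[tuple]:
    """Common-regulator pairs (canonical tuples) from a directed edge list."""
    targets_of: dict = {}
    for u, v in edges:
        targets_of.setdefault(u, []).append(v)
    crn_edges: set[tuple] = set()
    for targets in targets_of.values():
        for i in range(len(targets)):
            for j in range(i + 1, len(targets)):
                a, b = targets[i], targets[j]
                if a != b:
                    crn_edges.add((a, b) if a <= b else (b, a))
    return crn_edges


def crn_null(
    trn: RegulatoryNetwork,
    crn: CoregulatoryNetwork,
    embedding: CircularEmbedding,
    method: str = "crn_from_randomized_trn",
    base_trn_method: str = "edge_swap",
    intensity: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[CoregulatoryNetwork, CircularEmbedding]:
    """One randomized (CRN, embedding) replicate.

    ``crn_edge_swap`` swaps the CRN edges directly (degree sequence and edge
    count preserved).  ``crn_from_randomized_trn`` randomizes the TRN first
    (by ``base_trn_method``) and rebuilds the CRN from it; with an edge-swap
    base the CRN edge count is generally *not* preserved.
    """
    rng = _as_rng(seed)
    if set(crn.graph.nodes) != set(trn.graph.nodes):
        raise ValueError("CRN node set does not match the TRN it derives from")
    if method == "crn_edge_swap":
        edges = [tuple(sorted(e)) for e in crn.graph.edges]
        _swap_undirected(
            edges,
            int(round((intensity if intensity is not None else 10.0) * len(edges))),
            rng,
        )
        g = nx.Graph()
        g.add_nodes_from(crn.graph.nodes)
        g.add_edges_from(edges)
        return CoregulatoryNetwork(g, crn.level), embedding
    if method != "crn_from_randomized_trn":
        raise ValueError(f"unknown CRN null method {method!r}")
    if base_trn_method == "edge_swap":
        rand_trn = edge_swap_randomize(
            trn,
            intensity=intensity if intensity is not None else 10.0,
            seed=rng,
        )
        new_emb = embedding
    elif base_trn_method == "node_swap":
        rand_trn = trn
        new_emb = node_swap_randomize(
            embedding,
            swaps_per_node=intensity if intensity is not None else 100.0,
            seed=rng,
        )
    elif base_trn_method == "random_positions":
        rand_trn = trn
        new_emb = random_positions(embedding, seed=rng)
    else:
        raise ValueError(f"unknown base TRN method {base_trn_method!r}")
    g = nx.Graph()
    g.add_nodes_from(trn.graph.nodes)
    g.add_edges_from(_crn_edges_from_trn_edges(rand_trn.graph.edges))
    return CoregulatoryNetwork(g, crn.level), new_emb


def base_model_chain(
    network: RegulatoryNetwork,
    n_links: int,
    intensity: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> list[RegulatoryNetwork]:
    """Iterated randomization: network n is edge-swapped to give network n+1.

    Used as a consistency check that the switch randomizer is unbiased: the
    metric distribution along the chain should match that of independent
    replicates all derived from the original network.
    """
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    rng = _as_rng(seed)
    chain: list[RegulatoryNetwork] = []
    current = network
    for _ in range(n_links):
        current = edge_swap_randomize(current, intensity=intensity, seed=rng)
        chain.append(current)
    return chain


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class NullEnsemble:
    """A seeded collection of randomized replicates with per-replicate metrics.

    ``metrics`` has one row per replicate.  Replicate (network, embedding)
    pairs are only retained when the ensemble was generated with
    ``store_replicates=True``; metric records are always complete.
    """

    spec: NullModelSpec
    metrics: pd.DataFrame
    replicates: list = field(default_factory=list)
    replicate_seed_entropy: list = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.metrics)

    def null_values(self, metric: str) -> np.ndarray:
        return self.metrics[metric].to_numpy()


def _coded(network, embedding):
    """Integer-code nodes/edges and pull the angle array once."""
    nodes = list(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in network.graph.edges]
    angles = np.array([embedding.angles[n] for n in nodes], dtype=float)
    return nodes, index, edges, angles


def _distance_totals(edges: Sequence[tuple], angles: np.ndarray):
    if not edges:
        return 0.0, 0.0
    e = np.asarray(edges)
    gd = _angular_separation(angles[e[:, 0]], angles[e[:, 1]])
    return float(np.sum(2.0 * np.sin(gd / 2.0))), float(np.sum(gd))


def _graph_metrics(edges, n_nodes, directed, want_steps, want_span):
    """processing_steps / regulatory_span on an int-coded edge list."""
    from . import embedding_metrics as em

    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    wrapper = (
        RegulatoryNetwork(g) if directed else CoregulatoryNetwork(g)
    )
    steps = em.processing_steps(wrapper) if want_steps else math.nan
    span = (
        em.regulatory_span(wrapper)
        if (want_span and directed)
        else math.nan
    )
    return steps, span


def generate_ensemble(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    embedding: CircularEmbedding,
    spec: NullModelSpec,
    metrics: Sequence[str] = ("total_wiring_length", "total_genomic_distance"),
    trn: RegulatoryNetwork | None = None,
    store_replicates: bool = False,
) -> NullEnsemble:
    """Generate ``spec.n_replicates`` randomized replicates and record metrics.

    For the CRN methods, *network* is the CRN and ``crn_from_randomized_trn``
    additionally needs the parent TRN via ``trn=``.  Replicate seeds derive
    deterministically from ``spec.seed``, so identical specs give identical
    ensembles.
    """
    unknown = set(metrics) - set(ENSEMBLE_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    directed = isinstance(network, RegulatoryNetwork)
    if spec.method in ("crn_edge_swap", "crn_from_randomized_trn") and directed:
        raise ValueError(f"{spec.method} expects a CoregulatoryNetwork")
    if spec.method in ("edge_swap",) and not directed:
        raise ValueError("edge_swap expects a RegulatoryNetwork")
    if spec.method == "crn_from_randomized_trn" and trn is None:
        raise ValueError("crn_from_randomized_trn requires trn=")

    nodes, index, base_edges, base_angles = _coded(network, embedding)
    n_nodes = len(nodes)
    operon_of = None
    if directed and spec.forbid_within_operon and network.operon_map:
        operon_of = {
            index[n]: network.operon_map.get(n, n) for n in nodes
        }
    trn_edges = None
    if spec.method == "crn_from_randomized_trn":
        # TRN nodes may be a superset ordering; reuse the CRN node index
        trn_edges = [(index[u], index[v]) for u, v in trn.graph.edges]
        trn_operon_of = None
        if spec.forbid_within_operon and trn.operon_map:
            trn_operon_of = {index[n]: trn.operon_map.get(n, n) for n in nodes}

    want_steps = "processing_steps" in metrics
    want_span = "regulatory_span" in metrics
    seed_seqs = spec.replicate_seeds()
    rows = []
    stored = []
    for seq in seed_seqs:
        rng = np.random.default_rng(seq)
        edges = base_edges
        angles = base_angles
        if spec.method == "edge_swap":
            edges = list(base_edges)
            _swap_directed(
                edges, int(round(spec.intensity * len(edges))), rng, operon_of
            )
        elif spec.method == "crn_edge_swap":
            edges = [tuple(sorted(e)) for e in base_edges]
            _swap_undirected(
                edges, int(round(spec.intensity * len(edges))), rng
            )
        elif spec.method == "node_swap":
            values = base_angles.tolist()
            _swap_values(
                values, int(round(spec.intensity * n_nodes / 2.0)), rng
            )
            angles = np.asarray(values)
        elif spec.method == "random_positions":
            angles = rng.uniform(0.0, TWO_PI, size=n_nodes)
        elif spec.method == "crn_from_randomized_trn":
            if spec.base_trn_method == "edge_swap":
                redges = list(trn_edges)
                _swap_directed(
                    redges,
                    int(round(spec.intensity * len(redges))),
                    rng,
                    trn_operon_of,
                )
            else:
                redges = trn_edges
                if spec.base_trn_method == "node_swap":
                    values = base_angles.tolist()
                    _swap_values(
                        values, int(round(100.0 * n_nodes / 2.0)), rng
                    )
                    angles = np.asarray(values)
                elif spec.base_trn_method == "random_positions":
                    angles = rng.uniform(0.0, TWO_PI, size=n_nodes)
                else:
                    raise ValueError(
                        f"unknown base TRN method {spec.base_trn_method!r}"
                    )
            edges = sorted(_crn_edges_from_trn_edges(redges))

        wl, gd = _distance_totals(edges, angles)
        row = {"total_wiring_length": wl, "total_genomic_distance": gd}
        if want_steps or want_span:
            rep_directed = directed
            steps, span = _graph_metrics(
                edges, n_nodes, rep_directed, want_steps, want_span
            )
            row["processing_steps"] = steps
            row["regulatory_span"] = span
        rows.append(row)
        if store_replicates:
            stored.append(
                _materialize(nodes, edges, angles, directed, network.level,
                             embedding.genome_length_bp)
            )

    table = pd.DataFrame(rows)
    keep = [m for m in ENSEMBLE_METRICS if m in table.columns and m in
            set(metrics) | {"total_wiring_length", "total_genomic_distance"}]
    return NullEnsemble(
        spec=spec,
        metrics=table[keep],
        replicates=stored,
        replicate_seed_entropy=[s.entropy for s in seed_seqs],
    )


def _materialize(nodes, edges, angles, directed, level, genome_length_bp):
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((nodes[u], nodes[v]) for u, v in edges)
    net = (
        RegulatoryNetwork(g, level) if directed else CoregulatoryNetwork(g, level)
    )
    emb = CircularEmbedding(
        dict(zip(nodes, np.asarray(angles).tolist())), genome_length_bp
    )
    return net, emb
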