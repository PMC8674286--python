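"""Circular embedding of network nodes and the four performance indicators.

The chromosome is approximated as a unit circle in 2D.  A node's angle is
``2*pi * center_bp / genome_length_bp``.  Two distances are defined between
node centers: *wiring length* (WL), the Euclidean chord through the cell
interior, a proxy for 3D diffusion of a transcription factor; and *genomic
distance* (GD), the shorter arc along the chromosome, a proxy for 1D sliding
along DNA.  On the unit circle they are linked by ``WL = 2 sin(GD/2)``.

Connectivity indicators: *processing steps*, the mean shortest-path step
count (over reachable ordered pairs for a directed TRN, over the largest
connected component for an undirected CRN), and *regulatory span*, the mean
percentage of nodes reachable from a regulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import (
    ChromosomeMap,
    CoregulatoryNetwork,
    RegulatoryNetwork,
)

__all__ = [
    "CircularEmbedding",
    "NetworkMetrics",
    "embed_circular",
    "wiring_length",
    "genomic_distance",
    "edge_distances",
    "total_wiring_length",
    "total_genomic_distance",
    "processing_steps",
    "shortest_path_steps",
    "regulatory_span",
    "regulator_wiring_profile",
    "network_metrics",
]

TWO_PI = 2.0 * math.pi


@dataclass
class CircularEmbedding:
    """Node -> angle map on the unit circle (radians in [0, 2*pi))."""

    angles: dict[str, float]
    genome_length_bp: int = 0

    def __post_init__(self) -> None:
        self.angles = {n: float(a) % TWO_PI for n, a in self.angles.items()}

    def angle_array(self, nodes: Iterable[str]) -> np.ndarray:
        return np.array([self.angles[n] for n in nodes], dtype=float)

    def __contains__(self, node: str) -> bool:
        return node in self.angles

    def __len__(self) -> int:
        return len(self.angles)


def embed_circular(
    chromosome: ChromosomeMap, level: str = "gene"
) -> CircularEmbedding:
    """Angles from base-pair centers: theta = 2*pi * center / genome length."""
    L = chromosome.genome_length_bp
    if level == "gene":
        centers = {g: chromosome.gene_center_bp(g) for g in chromosome.genes}
    elif level == "operon":
        centers = {
            op: chromosome.operon_center_bp(op) for op in chromosome.operons
        }
    else:
        raise ValueError("level must be 'gene' or 'operon'")
    return CircularEmbedding(
        angles={n: TWO_PI * c / L for n, c in centers.items()},
        genome_length_bp=L,
    )


def _angular_separation(theta_a, theta_b):
    """Shortest angular separation, in [0, pi]; accepts scalars or arrays."""
    d = np.abs(np.asarray(theta_a) - np.asarray(theta_b)) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def wiring_length(theta_a, theta_b):
    """Chord distance between two unit-circle points: 2*sin(delta/2)."""
    out = 2.0 * np.sin(_angular_separation(theta_a, theta_b) / 2.0)
    return float(out) if np.isscalar(theta_a) and np.isscalar(theta_b) else out


def genomic_distance(theta_a, theta_b):
    """Shorter arc between two unit-circle points, in [0, pi]."""
    out = _angular_separation(theta_a, theta_b)
    return float(out) if np.isscalar(theta_a) and np.isscalar(theta_b) else out


def _edge_angles(network, embedding: CircularEmbedding):
    edges = list(network.graph.edges)
    missing = sorted(
        {n for e in edges for n in e if n not in embedding.angles}
        | {n for n in network.graph.nodes if n not in embedding.angles}
    )
    if missing:
        raise ValueError(f"nodes without an embedding angle: {missing}")
    if not edges:
        return edges, np.empty(0), np.empty(0)
    src = embedding.angle_array(e[0] for e in edges)
    tgt = embedding.angle_array(e[1] for e in edges)
    return edges, src, tgt


def edge_distances(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    embedding: CircularEmbedding,
) -> pd.DataFrame:
    """Per-edge wiring length and genomic distance.

    Column sums give the network totals.
    """
    edges, src, tgt = _edge_angles(network, embedding)
    gd = _angular_separation(src, tgt)
    return pd.DataFrame(
        {
            "source": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "wiring_length": 2.0 * np.sin(gd / 2.0),
            "genomic_distance": gd,
        }
    )


def total_wiring_length(network, embedding: CircularEmbedding) -> float:
    _, src, tgt = _edge_angles(network, embedding)
    return float(np.sum(2.0 * np.sin(_angular_separation(src, tgt) / 2.0)))


def total_genomic_distance(network, embedding: CircularEmbedding) -> float:
    _, src, tgt = _edge_angles(network, embedding)
    return float(np.sum(_angular_separation(src, tgt)))


def shortest_path_steps(network, source: str, target: str) -> int:
    """Step count of the shortest path between two nodes."""
    return nx.shortest_path_length(network.graph, source, target)


def processing_steps(
    network: RegulatoryNetwork | CoregulatoryNetwork,
) -> float:
    """Mean shortest-path step count.

    Directed network: mean over all ordered pairs (s, t), s != t, with a
    directed path from s to t.  Undirected network: mean over all unordered
    pairs inside the largest connected component.  NaN when no connected
    pair exists.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if g.is_directed():
        total = 0
        n_pairs = 0
        for s in g.nodes:
            lengths = nx.single_source_shortest_path_length(g, s)
            total += sum(lengths.values())  # distance to self is 0
            n_pairs += len(lengths) - 1
        return total / n_pairs if n_pairs else math.nan
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return math.nan
    sub = g.subgraph(comp)
    total = 0
    n_pairs = 0
    for s in sub.nodes:
        lengths = nx.single_source_shortest_path_length(sub, s)
        total += sum(lengths.values())
        n_pairs += len(lengths) - 1
    return total / n_pairs  # each unordered pair counted twice in both sums


def regulatory_span(
    network: RegulatoryNetwork, denominator: str = "n_minus_1"
) -> float:
    """Mean percentage of nodes reachable (directly or indirectly) from each
    regulator (node with out-degree >= 1).

    ``denominator='n_minus_1'`` excludes the regulator itself from the
    reference count (a node is never its own descendant); ``'n'`` divides by
    the full node count.  NaN when the network has no regulator.
    """
    g = network.graph
    n = g.number_of_nodes()
    regs = [v for v, d in g.out_degree() if d > 0]
    if not regs or n < 2:
        return math.nan
    denom = n - 1 if denominator == "n_minus_1" else n
    spans = [len(nx.descendants(g, r)) / denom for r in regs]
    return 100.0 * float(np.mean(spans))


def regulator_wiring_profile(
    network: RegulatoryNetwork, embedding: CircularEmbedding
) -> pd.DataFrame:
    """Per-regulator out-wiring statistics.

    One row per node with out-degree >= 1: out_degree, total_out_wiring
    (sum of outgoing-edge chords), max_out_wiring, mean_out_wiring.
    """
    dist = edge_distances(network, embedding)
    if dist.empty:
        return pd.DataFrame(
            columns=[
                "out_degree",
                "total_out_wiring",
                "max_out_wiring",
                "mean_out_wiring",
            ]
        )
    grouped = dist.groupby("source")["wiring_length"]
    profile = pd.DataFrame(
        {
            "out_degree": grouped.size(),
            "total_out_wiring": grouped.sum(),
            "max_out_wiring": grouped.max(),
            "mean_out_wiring": grouped.mean(),
        }
    )
    profile.index.name = "regulator"
    return profile.sort_index()


@dataclass
class NetworkMetrics:
    """The four performance indicators plus network size."""

    total_wiring_length: float
    total_genomic_distance: float
    processing_steps: float
    regulatory_span_pct: float
    n_nodes: int
    n_edges: int

    def to_dict(self) -> dict[str, float | int]:
        return {
            "total_wiring_length": self.total_wiring_length,
            "total_genomic_distance": self.total_genomic_distance,
            "processing_steps": self.processing_steps,
            "regulatory_span_pct": self.regulatory_span_pct,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }


def network_metrics(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    embedding: CircularEmbedding,
) -> NetworkMetrics:
    span = (
        regulatory_span(network)
        if isinstance(network, RegulatoryNetwork)
        else math.nan
    )
    return NetworkMetrics(
        total_wiring_length=total_wiring_length(network, embedding),
        total_genomic_distance=total_genomic_distance(network, embedding),
        processing_steps=processing_steps(network),
        regulatory_span_pct=span,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
    )
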