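"""Construction of the transcriptional regulatory network (TRN) and the
derived coregulatory network (CRN).

The TRN is a simple directed graph: nodes are genes (or operons) and an edge
points from the gene encoding a transcription factor to the gene it
regulates.  The CRN is the simple undirected graph linking every pair of
nodes that share at least one common regulator in the TRN.  Parsers accept
RegulonDB-style tab-separated interaction tables and a plain gene-position
table; all spatial information is carried by a :class:`ChromosomeMap`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "EFFECTS",
    "REGULONDB_EFFECT_CODES",
    "GeneRecord",
    "ChromosomeMap",
    "RegulatoryInteraction",
    "RegulatoryNetwork",
    "CoregulatoryNetwork",
    "ParseError",
    "ValidationError",
    "parse_interactions",
    "parse_chromosome",
    "build_trn",
    "build_crn",
    "write_edge_list",
    "network_to_json",
]

#: closed effect vocabulary
EFFECTS = ("activation", "repression", "dual", "unknown")

#: RegulonDB effect-code dialect: '+' activator, '-' repressor,
#: '+-'/'-+' dual, '?' unknown.
REGULONDB_EFFECT_CODES: Mapping[str, str] = {
    "+": "activation",
    "-": "repression",
    "−": "repression",  # unicode minus
    "+-": "dual",
    "-+": "dual",
    "+/-": "dual",
    "?": "unknown",
    "": "unknown",
    "activation": "activation",
    "repression": "repression",
    "dual": "dual",
    "unknown": "unknown",
}


class ParseError(ValueError):
    """Malformed input table (reported with the offending line number)."""


class ValidationError(ValueError):
    """Input violates a structural invariant (coordinates, ids, ...)."""


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One regulator -> target row of an interaction table."""

    regulator: str
    target: str
    effect: str = "unknown"

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValidationError(
                f"effect {self.effect!r} not in {EFFECTS}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene span on the circular chromosome, 1-based inclusive coordinates.

    A record with ``end_bp < start_bp`` spans the replication origin and is
    accepted (``wraps_origin`` is then true).
    """

    gene_id: str
    start_bp: int
    end_bp: int
    strand: str = "unknown"
    operon_id: str | None = None

    @property
    def wraps_origin(self) -> bool:
        return self.end_bp < self.start_bp


class ChromosomeMap:
    """Genome length plus gene records; the source of all node positions.

    Genes without an operon annotation are treated as singleton operons so
    that operon-level analyses are total.  Node centers are reported on a
    continuous 0-based coordinate in ``[0, genome_length_bp)``; the center of
    a span is the wrap-aware midpoint of its endpoint coordinates.
    """

    def __init__(
        self,
        genome_length_bp: int,
        genes: Iterable[GeneRecord],
        operons: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if genome_length_bp <= 0:
            raise ValidationError("genome_length_bp must be positive")
        self.genome_length_bp = int(genome_length_bp)
        self.genes: dict[str, GeneRecord] = {}
        for rec in genes:
            if rec.gene_id in self.genes:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            for coord in (rec.start_bp, rec.end_bp):
                if not 1 <= coord <= self.genome_length_bp:
                    raise ValidationError(
                        f"gene {rec.gene_id!r}: coordinate {coord} outside "
                        f"[1, {self.genome_length_bp}]"
                    )
            self.genes[rec.gene_id] = rec

        # explicit operon table wins; remaining annotated genes grouped by
        # their operon_id; everything else becomes a singleton operon
        self.operons: dict[str, list[str]] = {}
        if operons is not None:
            for op_id, members in operons.items():
                for g in members:
                    if g not in self.genes:
                        raise ValidationError(
                            f"operon {op_id!r} member {g!r} not a known gene"
                        )
                self.operons[op_id] = list(members)
        else:
            for g, rec in self.genes.items():
                if rec.operon_id is not None:
                    self.operons.setdefault(rec.operon_id, []).append(g)
        assigned = {g for members in self.operons.values() for g in members}
        if len(assigned) != sum(len(m) for m in self.operons.values()):
            raise ValidationError("a gene belongs to more than one operon")
        self._operon_of: dict[str, str] = {}
        for op_id, members in self.operons.items():
            for g in members:
                self._operon_of[g] = op_id
        for g in self.genes:
            if g not in assigned:
                self.operons[g] = [g]
                self._operon_of[g] = g

    # -- positions -----------------------------------------------------

    def span_center(self, start_bp: int, end_bp: int) -> float:
        """Wrap-aware midpoint of a 1-based inclusive span, mod genome length."""
        L = self.genome_length_bp
        return (start_bp + ((end_bp - start_bp) % L) / 2.0) % L

    def gene_center_bp(self, gene_id: str) -> float:
        rec = self.genes[gene_id]
        return self.span_center(rec.start_bp, rec.end_bp)

    def operon_center_bp(self, operon_id: str) -> float:
        """Midpoint of the span from the first member's start to the last
        member's end (wrap-aware); operon members are kept in input order."""
        members = self.operons[operon_id]
        first, last = self.genes[members[0]], self.genes[members[-1]]
        return self.span_center(first.start_bp, last.end_bp)

    def operon_of(self, gene_id: str) -> str:
        return self._operon_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RegulatoryNetwork:
    """Simple directed regulator -> target graph at gene or operon level."""

    graph: nx.DiGraph
    level: str = "gene"
    operon_map: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_effects(self) -> dict[tuple[str, str], str]:
        return {
            (u, v): d.get("effect", "unknown")
            for u, v, d in self.graph.edges(data=True)
        }

    def regulators(self) -> list[str]:
        """Nodes with out-degree >= 1."""
        return [n for n, d in self.graph.out_degree() if d > 0]


@dataclass
class CoregulatoryNetwork:
    """Simple undirected graph linking pairs of nodes sharing a regulator."""

    graph: nx.Graph
    level: str = "gene"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# parsers


def parse_interactions(
    path: str | Path,
    dialect: Mapping[str, str] = REGULONDB_EFFECT_CODES,
) -> list[RegulatoryInteraction]:
    """Read a tab-separated regulator/target/effect table.

    Lines starting with ``#`` are comments.  Effect codes are normalized via
    *dialect* (RegulonDB codes by default).  Row order is preserved and
    duplicates are kept — de-duplication happens in :func:`build_trn`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[RegulatoryInteraction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            reg, tgt, code = (f.strip() for f in fields[:3])
            if code not in dialect:
                raise ParseError(
                    f"{path}:{lineno}: unknown effect code {code!r}"
                )
            out.append(RegulatoryInteraction(reg, tgt, dialect[code]))
    return out


def parse_chromosome(path: str | Path, genome_length_bp: int) -> ChromosomeMap:
    """Read a gene-position table: gene_id, start, end[, strand[, operon]].

    A header line is detected by non-integer start/end fields and skipped.
    Validation (coordinate range, unique ids) is delegated to
    :class:`ChromosomeMap`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                if lineno == 1 or not records:
                    continue  # header row
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            strand = fields[3] if len(fields) > 3 and fields[3] else "unknown"
            operon = fields[4] if len(fields) > 4 and fields[4] else None
            records.append(GeneRecord(fields[0], start, end, strand, operon))
    return ChromosomeMap(genome_length_bp, records)


# ---------------------------------------------------------------------------
# network construction


def build_trn(
    interactions: Sequence[RegulatoryInteraction],
    level: str = "gene",
    chromosome: ChromosomeMap | None = None,
    include_isolates: bool = False,
) -> RegulatoryNetwork:
    """Build the simple directed TRN at the requested level.

    Duplicate (source, target) pairs collapse to one edge; conflicting effect
    annotations on a duplicate resolve to ``dual``.  Self-loops and edges
    whose source and target lie in the same operon are removed at both the
    gene and the operon level.  With ``include_isolates`` every positioned
    gene (or operon) enters the node set even if no interaction survives.
    """
    if level not in ("gene", "operon"):
        raise ValueError("level must be 'gene' or 'operon'")
    if chromosome is not None:
        missing = sorted(
            {g for it in interactions for g in (it.regulator, it.target)}
            - set(chromosome.genes)
        )
        if missing:
            raise ValidationError(
                f"interactions reference genes absent from chromosome: {missing}"
            )

    def node_of(gene: str) -> str:
        if level == "operon":
            return chromosome.operon_of(gene) if chromosome is not None else gene
        return gene

    def operon_of(gene: str) -> str | None:
        return chromosome.operon_of(gene) if chromosome is not None else None

    g = nx.DiGraph()
    for it in interactions:
        u, v = node_of(it.regulator), node_of(it.target)
        if u == v:
            continue  # self-loop (gene level) or within-operon (operon level)
        if level == "gene":
            ou, ov = operon_of(it.regulator), operon_of(it.target)
            if ou is not None and ou == ov:
                continue  # interaction originates and ends in the same operon
        if g.has_edge(u, v):
            if g[u][v]["effect"] != it.effect:
                g[u][v]["effect"] = "dual"
        else:
            g.add_edge(u, v, effect=it.effect)

    if include_isolates and chromosome is not None:
        if level == "gene":
            g.add_nodes_from(chromosome.genes)
        else:
            g.add_nodes_from(chromosome.operons)

    operon_map: dict[str, str] = {}
    if level == "gene" and chromosome is not None:
        operon_map = {n: chromosome.operon_of(n) for n in g.nodes}
    return RegulatoryNetwork(graph=g, level=level, operon_map=operon_map)


def build_crn(trn: RegulatoryNetwork) -> CoregulatoryNetwork:
    """Derive the coregulatory network: for every regulator r, every
    unordered pair of distinct out-neighbors of r becomes an edge."""
    g = nx.Graph()
    g.add_nodes_from(trn.graph.nodes)
    for r in trn.graph.nodes:
        targets = list(trn.graph.successors(r))
        for i in range(len(targets)):
            for j in range(i + 1, len(targets)):
                g.add_edge(targets[i], targets[j])
    return CoregulatoryNetwork(graph=g, level=trn.level)


# ---------------------------------------------------------------------------
# export


def write_edge_list(
    network: RegulatoryNetwork | CoregulatoryNetwork, path: str | Path
) -> None:
    """Write edges as a sorted two/three-column TSV (deterministic)."""
    directed = isinstance(network, RegulatoryNetwork)
    with open(path, "w") as fh:
        if directed:
            fh.write("source\ttarget\teffect\n")
            for u, v, d in sorted(network.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('effect', 'unknown')}\n")
        else:
            fh.write("node_a\tnode_b\n")
            for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
                fh.write(f"{u}\t{v}\n")


def network_to_json(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    provenance: Mapping[str, object] | None = None,
) -> str:
    directed = isinstance(network, RegulatoryNetwork)
    doc = {
        "level": network.level,
        "directed": directed,
        "nodes": sorted(network.graph.nodes),
        "edges": sorted(
            list(e) if directed else sorted(e) for e in network.graph.edges
        ),
        "provenance": dict(provenance or {}),
    }
    return json.dumps(doc, indent=1, sort_keys=True)
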