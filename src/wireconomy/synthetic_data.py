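"""Synthetic chromosomes, regulatory networks, gene sets and expression
matrices with controllable spatial structure.

The generator stands in for curated bacterial inputs (an interaction table,
a gene-position table, a genes x samples expression matrix, gene-set
definitions) so the whole pipeline is testable offline.  Three dials matter:

* ``locality_kappa`` — arc scale (radians) of the exponential kernel used to
  place a regulator's targets; small kappa gives spatially local regulation,
  ``inf`` gives position-independent wiring.
* ``coupling_rho`` — target Spearman correlation between a regulator's total
  out-wiring and its expression level, realized through a Gaussian copula:
  a latent normal score of the wiring rank is mixed with independent normal
  noise at Pearson weight ``r = 2 sin(pi * rho / 6)``, the bivariate-normal
  relation between Pearson and Spearman correlation.
* ``placement`` — ``uniform`` spreads operons evenly; ``clumped`` draws the
  intergenic gaps from a sparse Dirichlet so gene density is strongly
  nonuniform, mimicking real chromosomes.

All outputs are deterministic functions of the spec (each generation stage
draws from its own stream spawned from ``spec.seed``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding_metrics import embed_circular, genomic_distance
from .network_model import (
    ChromosomeMap,
    GeneRecord,
    RegulatoryInteraction,
    RegulatoryNetwork,
    build_trn,
)
from .stats_analysis import GeneSet

__all__ = [
    "SyntheticSpec",
    "generate_chromosome",
    "generate_trn",
    "generate_expression",
    "generate_genesets",
    "write_interactions_tsv",
    "write_chromosome_tsv",
    "write_expression_tsv",
    "write_gmt",
    "write_regulator_sidecar",
]

# per-stage RNG stream keys (spawned from spec.seed)
_STREAM = {"chromosome": 0, "trn": 1, "expression": 2, "genesets": 3}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale bacterial system: 500 genes on a
    4.64-Mb circular genome (the size of the E. coli K-12 chromosome),
    50 regulators with heavy-tailed out-degrees, spatially local targeting
    (kappa = 0.2 rad), geometric operon sizes (mean ~1.7 genes), and a
    278-sample expression matrix whose regulator rows are rank-coupled to
    out-wiring at Spearman 0.4.
    """

    n_genes: int = 500
    genome_length_bp: int = 4_641_652
    n_regulators: int = 50
    out_degree_law: str = "pareto"  # or "fixed"
    out_degree_param: float = 2.0  # pareto tail exponent, or the fixed degree
    locality_kappa: float = 0.2  # radians; math.inf = spatially random
    operon_size_p: float = 0.6  # geometric success prob; 1 -> all singletons
    placement: str = "uniform"  # or "clumped"
    n_samples: int = 278
    coupling_rho: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulators > self.n_genes:
            raise ValueError("n_regulators cannot exceed n_genes")
        if not (self.locality_kappa > 0):
            raise ValueError("locality_kappa must be > 0 (use inf for none)")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [0, 1]")
        if not 0.0 < self.operon_size_p <= 1.0:
            raise ValueError("operon_size_p must lie in (0, 1]")
        if self.out_degree_law not in ("pareto", "fixed"):
            raise ValueError("out_degree_law must be 'pareto' or 'fixed'")
        if self.placement not in ("uniform", "clumped"):
            raise ValueError("placement must be 'uniform' or 'clumped'")

    def stream(self, stage: str) -> np.random.Generator:
        key = _STREAM[stage]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


def generate_chromosome(spec: SyntheticSpec) -> ChromosomeMap:
    """Place genes on the circle, grouped into contiguous same-strand operons.

    Gene lengths are uniform on [300, 1500] bp with 20-bp intra-operon
    spacers; remaining length is distributed over inter-operon gaps
    (evenly-weighted Dirichlet for ``uniform`` placement, a sparse Dirichlet
    for ``clumped``).
    """
    rng = spec.stream("chromosome")
    n = spec.n_genes
    # operon sizes (geometric, mean 1/p) covering exactly n genes
    sizes: list[int] = []
    while sum(sizes) < n:
        sizes.append(int(rng.geometric(spec.operon_size_p)))
    sizes[-1] -= sum(sizes) - n
    if sizes[-1] == 0:
        sizes.pop()
    n_operons = len(sizes)

    gene_len = rng.integers(300, 1501, size=n)
    spacer = 20
    occupied = int(gene_len.sum()) + spacer * (n - n_operons)
    slack = spec.genome_length_bp - occupied - n_operons  # >=1 bp per gap
    if slack < 0:
        raise ValueError(
            f"{n} genes (+operon spacing) do not fit in "
            f"{spec.genome_length_bp} bp"
        )
    alpha = 1.0 if spec.placement == "uniform" else 0.05
    weights = rng.dirichlet(np.full(n_operons, alpha))
    gaps = 1 + np.floor(weights * slack).astype(int)
    gaps[-1] += spec.genome_length_bp - occupied - int(gaps.sum())

    records: list[GeneRecord] = []
    cursor = 1
    gi = 0
    for oi, size in enumerate(sizes):
        cursor += int(gaps[oi])
        strand = "+" if rng.random() < 0.5 else "-"
        op_id = f"op{oi:04d}"
        for k in range(size):
            start = cursor
            end = cursor + int(gene_len[gi]) - 1
            records.append(
                GeneRecord(f"g{gi:04d}", start, end, strand, op_id)
            )
            cursor = end + 1 + spacer
            gi += 1
        cursor -= spacer  # no spacer after the last gene of an operon
    return ChromosomeMap(spec.genome_length_bp, records)


def _draw_out_degrees(spec: SyntheticSpec, rng, cap: int) -> np.ndarray:
    if spec.out_degree_law == "fixed":
        return np.full(spec.n_regulators, int(spec.out_degree_param))
    # heavy-tailed: shifted discrete Pareto with tail exponent out_degree_param
    raw = 1 + np.floor(rng.pareto(spec.out_degree_param,
                                  size=spec.n_regulators)).astype(int)
    return np.clip(raw, 1, cap)


def generate_trn(
    spec: SyntheticSpec, chromosome: ChromosomeMap
) -> RegulatoryNetwork:
    """Sample a simple directed TRN with a tunable spatial locality kernel.

    Each regulator draws its targets without replacement with probability
    proportional to ``exp(-GD(regulator, candidate) / locality_kappa)``;
    self-targets and within-operon targets are excluded.
    """
    rng = spec.stream("trn")
    genes = list(chromosome.genes)
    embedding = embed_circular(chromosome)
    theta = np.array([embedding.angles[g] for g in genes])
    regulators = rng.choice(genes, size=spec.n_regulators, replace=False)
    degrees = _draw_out_degrees(spec, rng, cap=max(1, spec.n_genes // 4))

    interactions: list[RegulatoryInteraction] = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    for reg, d in zip(regulators, degrees):
        op = chromosome.operon_of(reg)
        mask = np.array(
            [g != reg and chromosome.operon_of(g) != op for g in genes]
        )
        candidates = np.flatnonzero(mask)
        if d > candidates.size:
            raise ValueError(
                f"regulator {reg}: {d} targets requested but only "
                f"{candidates.size} legal candidates"
            )
        if math.isinf(spec.locality_kappa):
            probs = None
        else:
            gd = genomic_distance(theta[gene_pos[reg]], theta[candidates])
            w = np.exp(-gd / spec.locality_kappa)
            probs = w / w.sum()
        chosen = rng.choice(candidates, size=int(d), replace=False, p=probs)
        for t in chosen:
            effect = "activation" if rng.random() < 0.5 else "repression"
            interactions.append(
                RegulatoryInteraction(reg, genes[t], effect)
            )
    return build_trn(interactions, level="gene", chromosome=chromosome)


def generate_expression(
    spec: SyntheticSpec,
    profile: pd.DataFrame,
    gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Genes x samples expression matrix coupled to regulator out-wiring.

    Regulator rows follow a Gaussian copula against the rank of
    ``total_out_wiring`` with target Spearman ``coupling_rho``; all other
    genes are independent noise around the baseline.  Values sit on a
    log-expression-like scale (baseline 8, sd ``noise_sd``); the scale is
    irrelevant to the rank-based downstream analysis.  ``coupling_rho = 1``
    yields an exactly monotone (noise-free) relation.
    """
    if profile.empty:
        raise ValueError("regulator wiring profile is empty")
    rng = spec.stream("expression")
    baseline = 8.0
    rho = spec.coupling_rho
    r = 2.0 * math.sin(math.pi * rho / 6.0)  # Pearson weight for the copula

    regulators = [g for g in profile.index if g in set(gene_ids)]
    wiring = profile.loc[regulators, "total_out_wiring"].to_numpy()
    ranks = pd.Series(wiring).rank(method="average").to_numpy()
    nreg = len(regulators)
    # Blom normal scores of the wiring ranks (the latent copula coordinate)
    from scipy.stats import norm

    latent = norm.ppf((ranks - 0.375) / (nreg + 0.25))

    samples = [f"s{j:03d}" for j in range(spec.n_samples)]
    values = np.empty((len(gene_ids), spec.n_samples))
    reg_row = {g: i for i, g in enumerate(gene_ids)}
    is_reg = np.zeros(len(gene_ids), dtype=bool)
    for g in regulators:
        is_reg[reg_row[g]] = True
    for j in range(spec.n_samples):
        noise = rng.standard_normal(len(gene_ids))
        col = baseline + spec.noise_sd * noise
        if rho >= 1.0:
            col[is_reg] = baseline + latent
        else:
            eps = rng.standard_normal(nreg)
            col[is_reg] = baseline + spec.noise_sd * (
                r * latent + math.sqrt(1.0 - r * r) * eps
            )
        values[:, j] = col
    return pd.DataFrame(values, index=list(gene_ids), columns=samples)


def generate_genesets(
    spec: SyntheticSpec,
    chromosome: ChromosomeMap,
    trn: RegulatoryNetwork,
    mode: str = "clustered",
    n_sets: int = 10,
    set_size: int = 8,
    arc: float = 0.1,
) -> list[GeneSet]:
    """Gene sets mimicking regulons (spatially clustered around a regulator)
    or iModulons (members drawn independently of position).

    Clustered sets take the ``set_size`` genes nearest to a seed regulator
    within an arc window of total width ``arc`` (so the maximum pairwise
    genomic distance inside a set is at most ``arc``); random sets sample
    members uniformly.  The seed (or a random) regulator is recorded as the
    set's main regulator.
    """
    if mode not in ("clustered", "random"):
        raise ValueError("mode must be 'clustered' or 'random'")
    if set_size > spec.n_genes:
        raise ValueError("set_size cannot exceed n_genes")
    rng = spec.stream("genesets")
    genes = list(chromosome.genes)
    embedding = embed_circular(chromosome)
    theta = np.array([embedding.angles[g] for g in genes])
    regulators = sorted(trn.regulators())
    if not regulators:
        raise ValueError("TRN has no regulators to seed gene sets")
    sets: list[GeneSet] = []
    for k in range(n_sets):
        seed_reg = regulators[int(rng.integers(len(regulators)))]
        if mode == "clustered":
            center = embedding.angles[seed_reg]
            gd = genomic_distance(np.full(len(genes), center), theta)
            in_window = np.flatnonzero(gd <= arc / 2.0)
            order = in_window[np.argsort(gd[in_window], kind="stable")]
            members = [genes[i] for i in order[:set_size]]
            kind = "regulon"
        else:
            members = list(
                rng.choice(genes, size=set_size, replace=False)
            )
            kind = "imodulon"
        sets.append(
            GeneSet(
                name=f"{kind}_{k:03d}",
                members=frozenset(members),
                main_regulators=frozenset({seed_reg}),
                kind=kind,
            )
        )
    return sets


# ---------------------------------------------------------------------------
# writers for the on-disk formats the parsers consume


_EFFECT_CODE = {"activation": "+", "repression": "-", "dual": "+-",
                "unknown": "?"}


def write_interactions_tsv(
    network: RegulatoryNetwork, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# regulator\ttarget\teffect\n")
        for (u, v), eff in sorted(network.edge_effects().items()):
            fh.write(f"{u}\t{v}\t{_EFFECT_CODE[eff]}\n")


def write_chromosome_tsv(chromosome: ChromosomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\toperon\n")
        for g in sorted(chromosome.genes):
            rec = chromosome.genes[g]
            fh.write(
                f"{rec.gene_id}\t{rec.start_bp}\t{rec.end_bp}\t"
                f"{rec.strand}\t{chromosome.operon_of(g)}\n"
            )


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def write_gmt(genesets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.kind}\t{members}\n")


def write_regulator_sidecar(
    genesets: Sequence[GeneSet], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# set\tmain_regulators\n")
        for gs in genesets:
            fh.write(f"{gs.name}\t{','.join(sorted(gs.main_regulators))}\n")
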