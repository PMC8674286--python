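"""End-to-end orchestration: build -> embed -> metrics -> null ensembles ->
z-scores -> expression correlation -> gene-set analysis.

A run is described by a single :class:`RunConfig` (loadable from YAML/JSON).
Inputs are either paths to the four on-disk tables or a synthetic spec; the
synthetic path writes the generated tables to the output directory and then
re-reads them, so the file round-trip is exercised on every run.  All
randomness derives from the master seed and every output file is written
deterministically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import synthetic_data as synth
from .embedding_metrics import (
    embed_circular,
    network_metrics,
    regulator_wiring_profile,
)
from .network_model import (
    build_crn,
    build_trn,
    network_to_json,
    parse_chromosome,
    parse_interactions,
    write_edge_list,
)
from .null_models import NullModelSpec
from .stats_analysis import (
    compare_to_null,
    expression_correlation,
    geneset_wiring,
    read_expression_tsv,
    read_gmt,
    read_regulator_sidecar,
)

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

logger = logging.getLogger("wireconomy")

DEFAULT_METRICS = ("total_wiring_length", "total_genomic_distance")


@dataclass
class RunConfig:
    """One serializable source of truth for a pipeline run."""

    output_dir: str
    seed: int = 0
    level: str = "gene"  # gene | operon | both
    # path inputs (exclusive with synthetic)
    interactions: str | None = None
    chromosome: str | None = None
    genome_length_bp: int | None = None
    expression: str | None = None
    genesets: str | None = None
    geneset_regulators: str | None = None
    # synthetic input
    synthetic: Mapping[str, Any] | None = None
    # analysis parameters
    null_methods: Sequence[str] = ("edge_swap", "node_swap", "random_positions")
    n_replicates: int = 1000
    metrics: Sequence[str] = DEFAULT_METRICS
    strict: bool = False

    def __post_init__(self) -> None:
        has_paths = self.interactions is not None or self.chromosome is not None
        if has_paths == (self.synthetic is not None):
            raise ValueError(
                "provide exactly one of {input paths, synthetic spec}"
            )
        if has_paths and (self.interactions is None or self.chromosome is None
                          or self.genome_length_bp is None):
            raise ValueError(
                "path inputs need interactions, chromosome and genome_length_bp"
            )
        if self.level not in ("gene", "operon", "both"):
            raise ValueError("level must be gene, operon or both")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "level": self.level,
            "interactions": self.interactions,
            "chromosome": self.chromosome,
            "genome_length_bp": self.genome_length_bp,
            "expression": self.expression,
            "genesets": self.genesets,
            "geneset_regulators": self.geneset_regulators,
            "synthetic": dict(self.synthetic) if self.synthetic else None,
            "null_methods": list(self.null_methods),
            "n_replicates": self.n_replicates,
            "metrics": list(self.metrics),
            "strict": self.strict,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    """Cross-file id consistency check (orphans are ids missing elsewhere)."""

    orphan_interaction_genes: list[str] = field(default_factory=list)
    missing_expression_regulators: int = 0
    unresolved_geneset_members: int = 0

    @property
    def clean(self) -> bool:
        return (
            not self.orphan_interaction_genes
            and self.missing_expression_regulators == 0
            and self.unresolved_geneset_members == 0
        )

    def to_dict(self) -> dict:
        return {
            "orphan_interaction_genes": self.orphan_interaction_genes,
            "missing_expression_regulators": self.missing_expression_regulators,
            "unresolved_geneset_members": self.unresolved_geneset_members,
            "clean": self.clean,
        }


def _load_inputs(config: RunConfig, outdir: Path):
    """Return (interactions, chromosome, expression|None, genesets|None)."""
    if config.synthetic is not None:
        spec = synth.SyntheticSpec(**{**config.synthetic,
                                      "seed": config.synthetic.get(
                                          "seed", config.seed)})
        chromosome = synth.generate_chromosome(spec)
        trn = synth.generate_trn(spec, chromosome)
        embedding = embed_circular(chromosome)
        profile = regulator_wiring_profile(trn, embedding)
        expression = synth.generate_expression(
            spec, profile, list(chromosome.genes)
        )
        genesets = synth.generate_genesets(spec, chromosome, trn)
        gen = outdir / "generated"
        gen.mkdir(parents=True, exist_ok=True)
        synth.write_interactions_tsv(trn, gen / "interactions.tsv")
        synth.write_chromosome_tsv(chromosome, gen / "chromosome.tsv")
        synth.write_expression_tsv(expression, gen / "expression.tsv")
        synth.write_gmt(genesets, gen / "genesets.gmt")
        synth.write_regulator_sidecar(genesets, gen / "geneset_regulators.tsv")
        interactions = parse_interactions(gen / "interactions.tsv")
        chromosome = parse_chromosome(
            gen / "chromosome.tsv", spec.genome_length_bp
        )
        expression = read_expression_tsv(gen / "expression.tsv")
        regs = read_regulator_sidecar(gen / "geneset_regulators.tsv")
        genesets = read_gmt(gen / "genesets.gmt", main_regulators=regs)
        return interactions, chromosome, expression, genesets
    interactions = parse_interactions(config.interactions)
    chromosome = parse_chromosome(config.chromosome, config.genome_length_bp)
    expression = (
        read_expression_tsv(config.expression) if config.expression else None
    )
    genesets = None
    if config.genesets:
        regs = (
            read_regulator_sidecar(config.geneset_regulators)
            if config.geneset_regulators
            else None
        )
        genesets = read_gmt(config.genesets, main_regulators=regs)
    return interactions, chromosome, expression, genesets


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Cross-check id consistency between the four input tables.

    Reports orphan counts; raises only in strict mode.
    """
    outdir = Path(config.output_dir)
    interactions, chromosome, expression, genesets = _load_inputs(
        config, outdir
    )
    report = ValidationReport()
    known = set(chromosome.genes)
    report.orphan_interaction_genes = sorted(
        {g for it in interactions for g in (it.regulator, it.target)} - known
    )
    if expression is not None:
        regulators = {it.regulator for it in interactions}
        report.missing_expression_regulators = len(
            regulators - set(expression.index)
        )
    if genesets is not None:
        report.unresolved_geneset_members = sum(
            len(gs.subgraph_nodes() - known) for gs in genesets
        )
    if config.strict and not report.clean:
        raise ValueError(f"strict validation failed: {report.to_dict()}")
    return report


def _analyze_level(
    level: str,
    interactions,
    chromosome,
    expression,
    genesets,
    config: RunConfig,
    outdir: Path,
) -> dict:
    """All analyses for one level (gene or operon); returns a manifest entry."""
    t0 = time.perf_counter()
    trn = build_trn(interactions, level=level, chromosome=chromosome)
    crn = build_crn(trn)
    embedding = embed_circular(chromosome, level=level)
    emb_view = type(embedding)(
        {n: embedding.angles[n] for n in trn.graph.nodes},
        embedding.genome_length_bp,
    )

    lvl_dir = outdir / level
    lvl_dir.mkdir(parents=True, exist_ok=True)
    write_edge_list(trn, lvl_dir / "trn_edges.tsv")
    write_edge_list(crn, lvl_dir / "crn_edges.tsv")
    (lvl_dir / "trn.json").write_text(
        network_to_json(trn, {"level": level, "seed": config.seed})
    )

    metrics = network_metrics(trn, emb_view)
    crn_metrics = network_metrics(crn, emb_view)
    (lvl_dir / "metrics.json").write_text(
        json.dumps(
            {"trn": metrics.to_dict(), "crn": crn_metrics.to_dict()},
            indent=1,
            sort_keys=True,
            allow_nan=True,
        )
    )

    zrows = []
    for method in config.null_methods:
        # stable per-(method, level) seed offset; process-salted hash() would
        # break cross-run determinism
        offset = zlib.crc32(f"{method}:{level}".encode()) % (2**20)
        spec = NullModelSpec(
            method=method,
            seed=config.seed + offset,
            n_replicates=config.n_replicates,
        )
        for res in compare_to_null(
            trn, emb_view, spec, metrics=config.metrics
        ):
            zrows.append({"network": "trn", **res.to_dict()})
    import pandas as pd

    pd.DataFrame(zrows).to_csv(lvl_dir / "zscores.tsv", sep="\t", index=False)
    logger.info("[%s] z-scores for %d null models written", level,
                len(config.null_methods))

    profile = regulator_wiring_profile(trn, emb_view)
    profile.to_csv(lvl_dir / "regulator_profile.tsv", sep="\t")

    entry: dict = {
        "trn_nodes": trn.n_nodes,
        "trn_edges": trn.n_edges,
        "crn_edges": crn.n_edges,
        "metrics": metrics.to_dict(),
        "zscores": zrows,
    }

    if expression is not None and level == "gene" and len(profile) >= 3:
        try:
            report = expression_correlation(
                expression, profile,
                predictors=("total_out_wiring", "max_out_wiring",
                            "out_degree", "mean_out_wiring"),
            )
        except ValueError as exc:
            logger.warning("[%s] expression correlation skipped: %s",
                           level, exc)
        else:
            report.table.to_csv(
                lvl_dir / "expression_correlation.tsv", sep="\t", index=False
            )
            report.summary.to_csv(
                lvl_dir / "expression_summary.tsv", sep="\t"
            )
            entry["expression_mean_rho"] = float(
                report.summary.loc["total_out_wiring", "mean_rho"]
            )

    if genesets and level == "gene":
        gs_spec = NullModelSpec(
            method="node_swap",
            seed=config.seed + 7,
            n_replicates=config.n_replicates,
        )
        result = geneset_wiring(trn, emb_view, genesets, gs_spec)
        result.per_set.to_csv(
            lvl_dir / "geneset_wiring.tsv", sep="\t", index=False
        )
        entry["geneset_total_wiring"] = result.total_wiring
        entry["geneset_z"] = result.zscore.z

    entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "levels": {},
    }
    try:
        report = validate_inputs(config)
        manifest["validation"] = report.to_dict()
        interactions, chromosome, expression, genesets = _load_inputs(
            config, outdir
        )
        levels = ["gene", "operon"] if config.level == "both" else [config.level]
        for level in levels:
            logger.info("stage=analyze level=%s", level)
            manifest["levels"][level] = _analyze_level(
                level, interactions, chromosome, expression, genesets,
                config, outdir,
            )
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest
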