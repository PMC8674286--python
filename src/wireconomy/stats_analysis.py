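"""Statistical layer: null-model z-scores, expression-wiring correlation,
and gene-set (regulon / iModulon style) spatial-compactness analysis.

A metric's z-score against a null ensemble is
``z = (observed - null_mean) / null_sd`` with the sample (n-1) standard
deviation; a strongly negative wiring-length z means the real network is
wired far more economically than chance.  Expression analysis follows the
rank-based route: per expression profile (sample), the Spearman correlation
between each regulator's out-wiring statistic and its own expression level.
Gene-set analysis sums the chord lengths of all edges induced by a set
(members plus their main regulators) and scores the collection total
against a node-swap ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .embedding_metrics import CircularEmbedding, wiring_length
from .network_model import CoregulatoryNetwork, RegulatoryNetwork
from .null_models import NullModelSpec, generate_ensemble

__all__ = [
    "ZScoreResult",
    "GeneSet",
    "CorrelationReport",
    "GeneSetWiringResult",
    "zscore",
    "compare_to_null",
    "spearman",
    "expression_correlation",
    "geneset_wiring",
    "read_expression_tsv",
    "read_gmt",
    "read_regulator_sidecar",
]

PREDICTORS = (
    "total_out_wiring",
    "max_out_wiring",
    "out_degree",
    "mean_out_wiring",
)


@dataclass(frozen=True)
class ZScoreResult:
    """Observed metric vs a null ensemble."""

    metric_name: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_replicates: int
    method: str = ""
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "n_replicates": self.n_replicates,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def zscore(
    observed: float,
    null_values: Sequence[float],
    metric_name: str = "",
    method: str = "",
) -> ZScoreResult:
    """z-score of an observation against null samples (sample SD, ddof=1).

    A zero-variance ensemble yields ``z = nan`` with the degenerate flag set
    (this happens by construction, e.g. for processing steps under position
    randomizations, which leave topology untouched).
    """
    vals = np.asarray(null_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 null values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        return ZScoreResult(
            metric_name, float(observed), mean, sd, math.nan,
            int(vals.size), method, degenerate=True,
        )
    return ZScoreResult(
        metric_name, float(observed), mean, sd,
        (float(observed) - mean) / sd, int(vals.size), method,
    )


def compare_to_null(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    embedding: CircularEmbedding,
    spec: NullModelSpec,
    metrics: Sequence[str] = ("total_wiring_length",),
    trn: RegulatoryNetwork | None = None,
) -> list[ZScoreResult]:
    """Observed-vs-null z-scores for the requested metrics under one null.

    Observed values are computed from the input pair; null distributions come
    from a freshly generated ensemble per ``spec``.
    """
    from . import embedding_metrics as em

    observed: dict[str, float] = {}
    for m in metrics:
        if m == "total_wiring_length":
            observed[m] = em.total_wiring_length(network, embedding)
        elif m == "total_genomic_distance":
            observed[m] = em.total_genomic_distance(network, embedding)
        elif m == "processing_steps":
            observed[m] = em.processing_steps(network)
        elif m == "regulatory_span":
            if not isinstance(network, RegulatoryNetwork):
                raise ValueError("regulatory_span needs a directed network")
            observed[m] = em.regulatory_span(network)
        else:
            raise ValueError(f"unknown metric {m!r}")
    ensemble = generate_ensemble(network, embedding, spec, metrics, trn=trn)
    return [
        zscore(observed[m], ensemble.null_values(m), m, spec.method)
        for m in metrics
    ]


# ---------------------------------------------------------------------------
# expression-wiring correlation


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with two-sided p.

    Uses the large-sample t approximation (scipy) for n >= 10 and an exact
    permutation p-value below that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan  # rank correlation undefined for constants
    rho, p = sps.spearmanr(x, y)
    if n < 10 and math.isfinite(rho):
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def _exact_spearman_p(x, y, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n).

    For fixed rank vectors rho is affine in S = sum(rx_perm * ry), so the
    full pairing-permutation distribution reduces to enumerating S.
    """
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = tuple(sps.rankdata(y))
    n = len(rx)
    sx, sy = rx.std(), np.std(ry)
    if sx == 0 or sy == 0:
        return 1.0
    denom = n * sx * sy
    offset = n * rx.mean() * np.mean(ry)
    thresh = abs(rho_obs) - 1e-12
    hits = total = 0
    for perm in permutations(rx.tolist()):
        s = sum(a * b for a, b in zip(perm, ry))
        if abs((s - offset) / denom) >= thresh:
            hits += 1
        total += 1
    return hits / total


@dataclass
class CorrelationReport:
    """Per-sample Spearman correlations plus cross-sample summaries.

    ``table`` columns: sample, predictor, spearman_rho, p_value.
    ``summary`` rows per predictor: mean_rho, mean_p, max_p, n_samples.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    n_regulators: int
    dropped_regulators: int = 0


def expression_correlation(
    expression: pd.DataFrame,
    profile: pd.DataFrame,
    predictors: Sequence[str] = ("total_out_wiring",),
    regulator_filter: Iterable[str] | None = None,
) -> CorrelationReport:
    """Correlate regulator out-wiring with regulator expression, per sample.

    *expression* is a genes x samples frame; *profile* a regulator-indexed
    frame from :func:`wireconomy.embedding_metrics.regulator_wiring_profile`.
    Only regulators present in both are used (dropped ones are counted);
    ``regulator_filter`` optionally restricts the regulator set further.
    """
    bad = set(predictors) - set(PREDICTORS)
    if bad:
        raise ValueError(f"unknown predictors {sorted(bad)}")
    regs = profile.index
    if regulator_filter is not None:
        keep = set(regulator_filter)
        regs = regs[[r in keep for r in regs]]
    common = [r for r in regs if r in expression.index]
    dropped = len(regs) - len(common)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} regulators shared between expression and "
            "wiring profile; need >= 3"
        )
    sub_expr = expression.loc[common]
    rows = []
    for predictor in predictors:
        pvals = profile.loc[common, predictor].to_numpy()
        for sample in expression.columns:
            rho, p = spearman(pvals, sub_expr[sample].to_numpy())
            rows.append(
                {
                    "sample": sample,
                    "predictor": predictor,
                    "spearman_rho": rho,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("predictor")
        .agg(
            mean_rho=("spearman_rho", "mean"),
            mean_p=("p_value", "mean"),
            max_p=("p_value", "max"),
            n_samples=("sample", "nunique"),
        )
        .loc[list(dict.fromkeys(predictors))]
    )
    return CorrelationReport(table, summary, len(common), dropped)


# ---------------------------------------------------------------------------
# gene sets


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (regulon, iModulon, or custom) with main regulators."""

    name: str
    members: frozenset[str]
    main_regulators: frozenset[str] = frozenset()
    kind: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def subgraph_nodes(self) -> frozenset[str]:
        """Members plus main regulators (the regulator is added if absent)."""
        return self.members | self.main_regulators


@dataclass
class GeneSetWiringResult:
    """Wiring of a gene-set collection with its node-swap null z-score."""

    per_set: pd.DataFrame  # name, kind, n_nodes, n_edges, wiring_length
    total_wiring: float
    zscore: ZScoreResult
    unresolved: dict[str, int] = field(default_factory=dict)


def _set_edge_indices(network, node_index, genesets):
    """For each set: list of (u_idx, v_idx) edges induced by its node set."""
    g = network.graph
    out = []
    for gs in genesets:
        nodes = [n for n in gs.subgraph_nodes() if n in node_index]
        sub = g.subgraph(nodes)
        out.append(
            (gs, nodes, [(node_index[u], node_index[v]) for u, v in sub.edges])
        )
    return out


def geneset_wiring(
    network: RegulatoryNetwork | CoregulatoryNetwork,
    embedding: CircularEmbedding,
    genesets: Sequence[GeneSet],
    spec: NullModelSpec | None = None,
) -> GeneSetWiringResult:
    """Subgraph wiring lengths of gene sets, scored against node-swap nulls.

    A set's subgraph consists of its members plus its main regulators; its
    wiring is the chord-length sum over edges with both endpoints inside.
    The collection total is compared with the same quantity under a
    position-shuffling (node swap) ensemble, matching the analysis that
    separates spatially localized regulons from position-indifferent
    iModulons.  Member ids missing from the network are dropped and counted.
    """
    if not genesets:
        raise ValueError("empty gene-set collection")
    if spec is None:
        spec = NullModelSpec(method="node_swap", seed=0, n_replicates=1000)
    if spec.method != "node_swap":
        raise ValueError("gene-set nulls use the node_swap method")
    nodes = list(network.graph.nodes)
    node_index = {n: i for i, n in enumerate(nodes)}
    angles = np.array([embedding.angles[n] for n in nodes], dtype=float)
    resolved = _set_edge_indices(network, node_index, genesets)
    unresolved = {
        gs.name: len(gs.subgraph_nodes()) - len(kept)
        for gs, kept, _ in resolved
        if len(kept) < len(gs.subgraph_nodes())
    }

    def collection_total(theta: np.ndarray) -> tuple[float, list[float]]:
        per = []
        for _, _, eidx in resolved:
            if eidx:
                e = np.asarray(eidx)
                per.append(
                    float(np.sum(wiring_length(theta[e[:, 0]], theta[e[:, 1]])))
                )
            else:
                per.append(0.0)
        return float(sum(per)), per

    observed_total, per_set_wl = collection_total(angles)
    per_set = pd.DataFrame(
        {
            "name": [gs.name for gs, _, _ in resolved],
            "kind": [gs.kind for gs, _, _ in resolved],
            "n_nodes": [len(kept) for _, kept, _ in resolved],
            "n_edges": [len(eidx) for _, _, eidx in resolved],
            "wiring_length": per_set_wl,
        }
    )

    # node-swap null on the full embedding; only the angle permutation matters
    n = len(nodes)
    nulls = []
    for seq in spec.replicate_seeds():
        rng = np.random.default_rng(seq)
        values = angles.tolist()
        from .null_models import _swap_values

        _swap_values(values, int(round(spec.intensity * n / 2.0)), rng)
        nulls.append(collection_total(np.asarray(values))[0])
    z = zscore(observed_total, nulls, "geneset_total_wiring", spec.method)
    return GeneSetWiringResult(per_set, observed_total, z, unresolved)


# ---------------------------------------------------------------------------
# readers


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dup}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    return df


def read_gmt(
    path: str | Path,
    kind: str = "custom",
    main_regulators: Mapping[str, Iterable[str]] | None = None,
) -> list[GeneSet]:
    """GMT reader: one set per line — name, description, member ids."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member"
                )
            name = fields[0]
            regs = frozenset((main_regulators or {}).get(name, ()))
            sets.append(
                GeneSet(name, frozenset(fields[2:]), regs, kind=kind)
            )
    return sets


def read_regulator_sidecar(path: str | Path) -> dict[str, list[str]]:
    """TSV mapping set name -> comma-separated main regulator ids."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            out[fields[0]] = [r for r in fields[1].split(",") if r]
    return out
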