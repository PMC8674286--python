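"""Null-model invariants: exact degree preservation under edge swap,
position-multiset preservation under node swap, uniformity of random
positions, CRN null constructions, and ensemble reproducibility."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from wireconomy import (
    ChromosomeMap,
    CircularEmbedding,
    GeneRecord,
    RegulatoryInteraction,
    RegulatoryNetwork,
    base_model_chain,
    build_crn,
    build_trn,
    crn_null,
    edge_swap_randomize,
    generate_ensemble,
    node_swap_randomize,
    processing_steps,
    random_positions,
    regulatory_span,
    total_wiring_length,
)
from wireconomy.null_models import NullModelSpec

from .conftest import random_digraph, random_embedding


def degree_sequences(net):
    return (dict(net.graph.in_degree()), dict(net.graph.out_degree()))


# ---------------------------------------------------------------------------
# edge swap


class TestEdgeSwap:
    def test_two_edge_swap_has_one_legal_outcome(self):
        net = RegulatoryNetwork(nx.DiGraph([("A", "B"), ("C", "D")]))
        seen_swapped = False
        for seed in range(20):
            out = edge_swap_randomize(net, intensity=5, seed=seed)
            assert out.edges in (
                {("A", "B"), ("C", "D")},
                {("A", "D"), ("C", "B")},
            )
            seen_swapped |= out.edges == {("A", "D"), ("C", "B")}
        assert seen_swapped  # the single legal move is actually reachable

    def test_degree_sequences_exactly_preserved(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            net = random_digraph(rng, 30, 120)
            out = edge_swap_randomize(net, intensity=10, seed=seed)
            assert degree_sequences(out) == degree_sequences(net)
            assert all(u != v for u, v in out.edges)
            assert out.n_edges == net.n_edges

    def test_within_operon_edges_never_created(self):
        genes = [
            GeneRecord(f"g{i}", 1 + 100 * i, 80 + 100 * i, "+", f"op{i // 2}")
            for i in range(20)
        ]
        chrom = ChromosomeMap(10_000, genes)
        rng = np.random.default_rng(2)
        inter = []
        while len(inter) < 60:
            u, v = rng.integers(0, 20, size=2)
            inter.append(RegulatoryInteraction(f"g{u}", f"g{v}"))
        net = build_trn(inter, "gene", chrom)
        for seed in range(20):
            out = edge_swap_randomize(net, intensity=10, seed=seed)
            for u, v in out.edges:
                assert chrom.operon_of(u) != chrom.operon_of(v)

    def test_single_edge_returned_unchanged_with_warning(self):
        net = RegulatoryNetwork(nx.DiGraph([("A", "B")]))
        out = edge_swap_randomize(net, seed=0)
        assert out.edges == net.edges
        assert "swap_warning" in out.graph.graph

    def test_randomization_actually_moves_edges(self):
        rng = np.random.default_rng(3)
        net = random_digraph(rng, 40, 200)
        overlaps = []
        for seed in range(30):
            out = edge_swap_randomize(net, intensity=10, seed=seed)
            inter = len(net.edges & out.edges)
            union = len(net.edges | out.edges)
            overlaps.append(inter / union)
        assert np.mean(overlaps) < 0.5  # Jaccard well below half on average


# ---------------------------------------------------------------------------
# node swap / random positions


class TestNodeSwap:
    def test_two_nodes_one_swap_exchanges_angles(self):
        emb = CircularEmbedding({"a": 0.5, "b": 2.5})
        out = node_swap_randomize(emb, swaps_per_node=1, seed=0)
        assert out.angles == {"a": 2.5, "b": 0.5}

    def test_angle_multiset_preserved(self):
        rng = np.random.default_rng(4)
        emb = random_embedding(rng, [f"n{i}" for i in range(50)])
        out = node_swap_randomize(emb, swaps_per_node=100, seed=1)
        assert sorted(out.angles.values()) == pytest.approx(
            sorted(emb.angles.values())
        )
        assert set(out.angles) == set(emb.angles)

    def test_single_node_unchanged(self):
        emb = CircularEmbedding({"a": 1.0})
        assert node_swap_randomize(emb, seed=0).angles == emb.angles

    def test_assignment_decorrelates(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(100)]
        emb = random_embedding(rng, nodes)
        base = [emb.angles[n] for n in nodes]
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            out = node_swap_randomize(emb, swaps_per_node=100, seed=seed)
            rho = sps.spearmanr(base, [out.angles[n] for n in nodes]).statistic
            ok += abs(rho) < 0.3
        assert ok >= 0.9 * n_seeds

    def test_topology_untouched_so_steps_and_span_are_constant(self):
        rng = np.random.default_rng(6)
        net = random_digraph(rng, 25, 60)
        emb = random_embedding(rng, net.nodes)
        spec = NullModelSpec("node_swap", seed=7, n_replicates=5)
        ens = generate_ensemble(
            net, emb, spec, metrics=("processing_steps", "regulatory_span")
        )
        # every replicate has the original topology, hence identical values
        assert set(ens.null_values("processing_steps")) == {
            processing_steps(net)
        }
        assert set(ens.null_values("regulatory_span")) == {
            regulatory_span(net)
        }


class TestRandomPositions:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        emb = random_embedding(rng, "abcdef")
        a = random_positions(emb, seed=42)
        b = random_positions(emb, seed=42)
        assert a.angles == b.angles
        assert a.angles != emb.angles

    def test_empty_embedding(self):
        out = random_positions(CircularEmbedding({}), seed=0)
        assert len(out) == 0

    def test_pooled_angles_are_uniform(self):
        rng = np.random.default_rng(9)
        emb = random_embedding(rng, [f"n{i}" for i in range(200)])
        pooled = []
        for seed in range(10):
            pooled.extend(random_positions(emb, seed=seed).angles.values())
        stat = sps.kstest(
            np.array(pooled) / (2 * math.pi), "uniform"
        )
        assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# CRN nulls


def modular_trn(rng, n_regs=12, block=12, n_genes=120):
    """Regulators targeting shared blocks -> strongly modular CRN."""
    genes = [f"g{i}" for i in range(n_genes)]
    g = nx.DiGraph()
    g.add_nodes_from(genes)
    for r in range(n_regs):
        reg = genes[r]
        lo = (r % (n_genes // block)) * block
        members = [m for m in genes[lo : lo + block] if m != reg]
        for m in members:
            g.add_edge(reg, m)
    return RegulatoryNetwork(g)


class TestCrnNull:
    def test_crn_edge_swap_preserves_degree_sequence(self):
        rng = np.random.default_rng(10)
        trn = random_digraph(rng, 20, 60)
        crn = build_crn(trn)
        emb = random_embedding(rng, crn.nodes)
        out, _ = crn_null(trn, crn, emb, method="crn_edge_swap", seed=11)
        assert dict(out.graph.degree()) == dict(crn.graph.degree())
        assert out.n_edges == crn.n_edges

    def test_node_swap_base_keeps_crn_topology(self):
        rng = np.random.default_rng(12)
        trn = random_digraph(rng, 15, 40)
        crn = build_crn(trn)
        emb = random_embedding(rng, crn.nodes)
        out, new_emb = crn_null(
            trn, crn, emb, method="crn_from_randomized_trn",
            base_trn_method="node_swap", seed=13,
        )
        assert out.edges == crn.edges
        assert sorted(new_emb.angles.values()) == pytest.approx(
            sorted(emb.angles.values())
        )
        assert new_emb.angles != emb.angles

    def test_edge_swap_base_inflates_crn_edges_on_modular_trn(self):
        rng = np.random.default_rng(14)
        trn = modular_trn(rng)
        crn = build_crn(trn)
        emb = random_embedding(rng, crn.nodes)
        counts = []
        for seed in range(20):
            out, _ = crn_null(
                trn, crn, emb, method="crn_from_randomized_trn",
                base_trn_method="edge_swap", seed=seed,
            )
            counts.append(out.n_edges)
        # destroying modularity scatters shared-target blocks -> more pairs
        assert np.mean(counts) > crn.n_edges

    def test_mismatched_node_sets_rejected(self):
        rng = np.random.default_rng(15)
        trn = random_digraph(rng, 10, 20)
        other = random_digraph(rng, 12, 20)
        crn = build_crn(other)
        emb = random_embedding(rng, crn.nodes)
        with pytest.raises(ValueError, match="node set"):
            crn_null(trn, crn, emb, seed=0)


# ---------------------------------------------------------------------------
# base-model chain


class TestBaseModelChain:
    def test_single_link_equals_one_swap_call(self):
        rng = np.random.default_rng(16)
        net = random_digraph(rng, 20, 60)
        chain = base_model_chain(net, n_links=1, seed=99)
        direct = edge_swap_randomize(net, seed=99)
        assert chain[0].edges == direct.edges

    def test_degree_sequences_constant_along_chain(self):
        rng = np.random.default_rng(17)
        net = random_digraph(rng, 25, 80)
        for link in base_model_chain(net, n_links=10, seed=5):
            assert degree_sequences(link) == degree_sequences(net)

    def test_chain_consistent_with_independent_ensemble(self):
        rng = np.random.default_rng(18)
        net = random_digraph(rng, 40, 150)
        emb = random_embedding(rng, net.nodes)
        chain_wl = [
            total_wiring_length(link, emb)
            for link in base_model_chain(net, n_links=50, seed=6)
        ]
        spec = NullModelSpec(method="edge_swap", seed=7, n_replicates=50)
        indep = generate_ensemble(net, emb, spec)
        indep_wl = indep.null_values("total_wiring_length")
        pooled_sd = math.sqrt(
            (np.var(chain_wl, ddof=1) + np.var(indep_wl, ddof=1)) / 2
        )
        assert abs(np.mean(chain_wl) - np.mean(indep_wl)) < 2 * pooled_sd


# ---------------------------------------------------------------------------
# ensembles


class TestGenerateEnsemble:
    def test_replicate_count_and_provenance(self):
        rng = np.random.default_rng(19)
        net = random_digraph(rng, 15, 40)
        emb = random_embedding(rng, net.nodes)
        spec = NullModelSpec(method="edge_swap", seed=1, n_replicates=3)
        ens = generate_ensemble(net, emb, spec, store_replicates=True)
        assert ens.n_replicates == 3
        assert len(ens.replicates) == 3
        assert len(ens.replicate_seed_entropy) == 3
        for rep_net, _ in ens.replicates:
            assert degree_sequences(rep_net) == degree_sequences(net)

    def test_same_spec_reproduces_byte_identical_metrics(self):
        rng = np.random.default_rng(20)
        net = random_digraph(rng, 20, 60)
        emb = random_embedding(rng, net.nodes)
        spec = NullModelSpec(method="node_swap", seed=2, n_replicates=10)
        a = generate_ensemble(net, emb, spec)
        b = generate_ensemble(net, emb, spec)
        assert a.metrics.equals(b.metrics)

    def test_node_swap_wl_varies_and_brackets_random_positions(self):
        # under uniform placement the node-swap and random-position nulls
        # sample the same wiring-length distribution up to density effects
        rng = np.random.default_rng(21)
        net = random_digraph(rng, 60, 200)
        emb = random_embedding(rng, net.nodes)  # uniform angles
        ns = generate_ensemble(
            net, emb, NullModelSpec("node_swap", seed=3, n_replicates=200)
        ).null_values("total_wiring_length")
        rp = generate_ensemble(
            net, emb,
            NullModelSpec("random_positions", seed=4, n_replicates=200),
        ).null_values("total_wiring_length")
        assert np.var(ns) > 0
        assert abs(np.mean(ns) - np.mean(rp)) < 3 * np.std(rp, ddof=1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown null-model method"):
            NullModelSpec(method="shuffle_everything")

    def test_crn_ensemble_requires_parent_trn(self):
        rng = np.random.default_rng(22)
        trn = random_digraph(rng, 10, 25)
        crn = build_crn(trn)
        emb = random_embedding(rng, crn.nodes)
        spec = NullModelSpec("crn_from_randomized_trn", seed=5, n_replicates=2)
        with pytest.raises(ValueError, match="trn"):
            generate_ensemble(crn, emb, spec)
        ens = generate_ensemble(crn, emb, spec, trn=trn)
        assert ens.n_replicates == 2
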