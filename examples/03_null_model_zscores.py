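"""Score a network's wiring economy against the three null models.

Edge swap preserves every node's in/out-degree but rewires partners; node
swap shuffles which node sits at which chromosomal position (keeping the
position multiset, hence gene density); random positions draws fresh
uniform angles.  A strongly negative wiring-length z-score under all three
means the real (here: locality-generated) network is wired far more
economically than chance.
"""

from wireconomy import (
    CircularEmbedding,
    NullModelSpec,
    SyntheticSpec,
    compare_to_null,
    embed_circular,
    generate_chromosome,
    generate_trn,
)

spec = SyntheticSpec(
    n_genes=500, n_regulators=50, out_degree_law="fixed",
    out_degree_param=24, locality_kappa=0.05, seed=42,
)
chromosome = generate_chromosome(spec)
trn = generate_trn(spec, chromosome)
full = embed_circular(chromosome)
embedding = CircularEmbedding(
    {n: full.angles[n] for n in trn.graph.nodes}, full.genome_length_bp
)

print(f"TRN: {trn.n_nodes} nodes, {trn.n_edges} edges (kappa=0.05)")
for method in ("edge_swap", "node_swap", "random_positions"):
    null = NullModelSpec(method, seed=1, n_replicates=200)
    (res,) = compare_to_null(
        trn, embedding, null, metrics=("total_wiring_length",)
    )
    print(
        f"{method:17s} observed={res.observed:8.1f} "
        f"null={res.null_mean:8.1f} +- {res.null_sd:6.1f}  z={res.z:7.2f}"
    )
# z << 0 under every null: the locality kernel produces the same signature
# of high wiring economy that distinguishes a real bacterial TRN.
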