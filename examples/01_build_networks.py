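"""Build a transcriptional regulatory network (TRN) and its coregulatory
network (CRN) from a RegulonDB-style interaction table.

The TRN edge points from the gene encoding a transcription factor to its
target; the CRN links every pair of genes sharing a regulator.  Edges that
start and end inside one operon are removed, as is any duplicate row.
"""

from wireconomy import (
    ChromosomeMap,
    GeneRecord,
    RegulatoryInteraction,
    build_crn,
    build_trn,
)

chromosome = ChromosomeMap(
    genome_length_bp=10_000,
    genes=[
        GeneRecord("acrR", 100, 700, "+", "acrR"),
        GeneRecord("acrA", 800, 1900, "-", "acrAB"),
        GeneRecord("acrB", 1950, 5000, "-", "acrAB"),
        GeneRecord("marA", 6000, 6500, "+", "marRAB"),
        GeneRecord("soxS", 8000, 8400, "+", "soxS"),
    ],
)

interactions = [
    RegulatoryInteraction("acrR", "acrB", "repression"),
    RegulatoryInteraction("acrR", "acrB", "repression"),  # duplicate row
    RegulatoryInteraction("acrA", "acrB", "activation"),  # within-operon
    RegulatoryInteraction("marA", "acrA", "activation"),
    RegulatoryInteraction("marA", "acrB", "activation"),
    RegulatoryInteraction("soxS", "acrB", "activation"),
]

gene_trn = build_trn(interactions, level="gene", chromosome=chromosome)
operon_trn = build_trn(interactions, level="operon", chromosome=chromosome)
crn = build_crn(gene_trn)

print(f"gene-level TRN:   {gene_trn.n_nodes} nodes, {gene_trn.n_edges} edges")
print(f"operon-level TRN: {operon_trn.n_nodes} nodes, {operon_trn.n_edges} edges")
print(f"gene-level CRN:   {crn.n_edges} coregulated pairs")
print(f"CRN pairs: {sorted(tuple(sorted(e)) for e in crn.edges)}")
# The duplicate and the within-operon acrA->acrB rows are dropped; acrB is
# targeted by acrR, marA and soxS, so those targets' partners form the CRN.
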