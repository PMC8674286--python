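# Methods

## Geometry

The circular chromosome is idealized as a unit circle in 2D. Input gene
coordinates are 1-based inclusive base pairs; a gene's center is the
wrap-aware midpoint of its endpoint coordinates, `(start + ((end − start)
mod L)/2) mod L`, so a gene spanning the replication origin (end < start) is
handled without special cases. An operon's position is the midpoint of the
span from its first member's start to its last member's end. Node angles
are `2π·center/L`; all distances are dimensionless on the unit circle
(chord ∈ [0, 2], arc ∈ [0, π], with chord = 2·sin(arc/2)).

## Network construction

The TRN is a simple directed graph. Duplicate (source, target) rows
collapse to one edge; when duplicates disagree on sign the retained edge is
annotated `dual` — the analysis is purely topological/geometric, so effect
signs are carried as annotation only. Self-loops and edges starting and
ending in the same operon are removed at both the gene and the operon
level. Genes without an operon annotation are treated as singleton operons,
which makes the within-operon rule total and reduces it to self-loop
removal for unannotated genes. The TRN node set defaults to genes appearing
in surviving interactions; an `include_isolates` flag adds all positioned
genes. The CRN contains an edge {u, v} whenever some regulator targets both
u and v; its node set is copied from the TRN.

## Performance indicators

- *Total wiring length / genomic distance*: sums of per-edge chords / arcs.
- *Processing steps*: mean shortest-path step count. For the directed TRN
  the mean runs over all reachable ordered pairs (unreachable pairs are
  ignored rather than assigned infinite length, keeping the mean finite); a
  configuration restricting to a giant component was considered but the
  reachable-pairs reading is the default. For the undirected CRN the mean
  runs over all pairs inside the largest connected component.
- *Regulatory span*: for each node with out-degree ≥ 1, the fraction of the
  other N − 1 nodes among its descendants, averaged and ×100. The N − 1
  denominator (a node is never its own descendant) is the default;
  `denominator="n"` is available, the difference is < 0.2 % at realistic
  network sizes. Because the regulator set is re-derived from the current
  network, the span responds to edge-swap randomization, as it should.

## Null models

- *Edge swap* (switch randomization): attempted swaps = intensity × |E|,
  default intensity 10 attempted swaps per edge (chosen from pilot runs
  showing edge-set Jaccard overlap with the original well under 50 %;
  exposed as a parameter). A swap (a→b, c→d) ⇒ (a→d, c→b) is rejected —
  counted against the budget, not retried — if it would create a self-loop,
  a parallel edge, or (default on, configurable) a within-operon edge.
  In- and out-degree sequences are preserved exactly.
- *Node swap*: `round(swaps_per_node × N / 2)` transpositions of two
  distinct nodes' positions, default 100 swaps per node. Topology and the
  angle multiset are preserved exactly, hence processing steps and
  regulatory span are bit-identical to the original's (z-scores for them
  are reported as zero-variance degenerate).
- *Random positions*: i.i.d. Uniform[0, 2π) angles. Preserves topology but
  not the (possibly highly nonuniform) gene-density profile — the node-swap
  null is the density-preserving alternative.
- *CRN nulls*: either an undirected degree-preserving swap of the CRN
  itself (edge count conserved), or rebuilding the CRN from a randomized
  TRN (edge count not conserved; on modular networks this inflates the CRN
  edge count, a property verified by test).
- *Base-model chain*: network n is edge-swapped to produce network n + 1;
  chain metric distributions matching those of independent replicates is
  the unbiasedness check.

Ensembles default to 1000 replicates (configurable 100–4000). Replicate k
draws its generator from `SeedSequence(master_seed).spawn()[k]`, making
ensembles reproducible, order-independent and parallelizable.

## Statistics

z = (observed − null mean)/null SD with the sample (n−1) SD; at 1000
replicates the ddof choice is negligible and it is the honest small-ensemble
estimator. Zero-variance ensembles yield a flagged degenerate result rather
than ±∞. A "wiring length average z-score" across null models is the plain
mean of per-model z values. Spearman correlations are tie-corrected; p
values use the large-sample t approximation for n ≥ 10 and an exact pairing
permutation enumeration below that (rho is affine in Σ rank·rank, so the
enumeration is cheap). No multiple-testing correction is applied across
expression profiles by default (per-profile p values plus their mean and
max are reported); gene-set wiring uses the node-swap null, the choice that
isolates *where the set's genes sit* from *how the network is wired*.

## Synthetic generator

The generator emulates the four curated inputs. Chromosome: gene lengths
uniform on [300, 1500] bp, 20-bp intra-operon spacers, geometric operon
sizes (default p = 0.6, mean ≈ 1.7 genes — typical of bacterial operon
annotations), inter-operon gaps from a Dirichlet (concentration 1 for
uniform placement, 0.05 for clumped density). Default scale is 500 genes on
a 4.64-Mb genome (the *E. coli* K-12 chromosome length) with 50 regulators
and heavy-tailed (discrete Pareto, exponent 2) out-degrees. TRN: each
regulator samples targets without replacement with probability ∝
exp(−GD/κ); κ defaults to 0.2 rad and κ = ∞ gives position-independent
wiring. Expression: a Gaussian copula couples the rank of a regulator's
total out-wiring to its expression at target Spearman ρ (default 0.4, the
magnitude of the published wiring–expression correlation) via the
bivariate-normal relation r = 2·sin(πρ/6); 278 samples by default,
matching the size of the published compendium of *E. coli* RNA-seq
profiles; ρ = 1 short-circuits to an exactly monotone noise-free map.
Gene sets: clustered mode takes the set-size genes nearest a seed regulator
within an arc window (regulon-like), random mode samples members uniformly
(iModulon-like).

What the generator does **not** emulate: the real *E. coli* degree
distribution and operon structure, transcription-unit overlap, sigma
factors, the Ori–Ter organization of gene density, or any 3D nucleoid
geometry. Passing tests therefore demonstrate that the pipeline detects the
spatial signals it is pointed at, not that those signals have the measured
*E. coli* effect sizes; headline values published for the real network
(e.g. wiring z-scores near −14 at gene level, span 10.4 % vs 28.2 %,
mean Spearman 0.4165, 4601 interactions / 1841 genes) require the actual
curated inputs, which the file readers accept.

## Numerical and design choices

- Angles are reduced mod 2π on construction; angular separation is computed
  as `min(d, 2π − d)` with d = |θ₁ − θ₂| mod 2π, exact at the 1e−12 level
  required by the chord–arc identity tests.
- The z-score self-calibration check draws the "observed" embedding from
  the uniform-position null and scores it against a uniform-position
  ensemble — the one null whose draw distribution can be sampled exactly,
  making the check a true calibration rather than an approximation.
- Verification problem sizes (e.g. 200-replicate ensembles, 20–50 seeds for
  repeated-seed checks, 500-gene networks) are the package's desk-scale
  defaults for fast, reproducible validation; ensemble sizes for real
  analyses default to 1000 replicates.
- Pipeline determinism: every randomized stage seeds from the master seed
  via stable CRC-based offsets per (null model, level); rerunning a config
  reproduces byte-identical output files.
- Degenerate inputs: networks with < 2 edges are returned unchanged from
  the edge swapper with a warning flag; empty embeddings, edgeless
  networks, and regulator-free networks return empty tables or NaN markers
  rather than raising.

## Known limitations

- The circle approximation ignores nucleoid 3D structure and its
  fluctuations; distances are lower-bound proxies for true search times.
- Composite (heteromeric) regulator identifiers in interaction tables are
  treated as single node ids.
- The exact attempted-swap budget used in published analyses of the real
  network is not documented; the default here (10 per edge) is validated by
  decorrelation tests but remains a parameter.
- No null model currently preserves multi-scale genomic-distance
  distributions; nulls randomize either wiring or positions wholesale.
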