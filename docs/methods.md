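# Methods

## Data model

The species–family (SF) matrix is a non-negative integer matrix with gene
families in rows and species in columns; entry (i, j) is the number of
genes of family *i* in species *j*. Orientation is fixed — the reader
rejects rather than guesses — and duplicate family or species labels are an
error, never silently merged. Families that are absent from every species
in a sub-selection are retained: all-zero rows contribute nothing to any
index, and dropping them would silently change the family universe between
analyses. Genus annotation is optional; operations that need it
(topology comparison, genus-coloured exports) fail fast with a clear
message rather than degrading.

Binarisation maps a count column to a presence/absence profile (bit = 1
iff count ≥ 1). The Venn-region counts of a species triplet (a, b, c, ab,
ac, bc, abc, and the three private regions) are validated against the
inclusion–exclusion identities on construction, so an inconsistent region
decomposition cannot circulate.

## Similarity indices

Four indices are implemented: 2-way and 3-way Sørensen (on binarised
profiles) and 2-way and 3-way Czekanowski (on raw counts); formulas are in
the README. Degenerate input — all profiles empty, denominator zero — is
defined to give index 0 rather than NaN: empty genomes share nothing, and
downstream pruning treats 0 as no-edge. Indices are computed in double
precision with no internal tolerance; tests that compare dual computation
routes use explicit bounds (1e−12 for the binary-reduction identity).

Two bounds justify the default pruning threshold and are enforced as
executable tests rather than assumed:

* if abc = 0 (no family in all three species), S₃ ≤ 3/4, with equality
  exactly when the three private regions are empty — verified exhaustively
  over all binary triples on a 4-family universe;
* if Σᵢ min(Xᵢ,Yᵢ,Zᵢ) = 0, C₃ ≤ 3/4 — verified over 10⁴ random conditioned
  count triples, with a constructed triple attaining the bound. The
  underlying inequality min(a,b) + min(a,c) − min(a,b,c) ≤ a is property-
  tested separately.

Hence any threshold strictly above 0.75 keeps only triplets whose weight
provably includes a three-way intersection contribution; 0.76 is the
package default.

The reciprocal-E-value pair score is −log₁₀((E_ab + E_ba)/2). The log base
and sign convention for this score vary across descriptions in the
literature; negative log₁₀ of the mean E-value is the convention adopted
here (it makes stronger hits score higher, in familiar "e-value exponent"
units). Underflowed E-values reported as exactly 0 by aligners are clamped
at a configurable ceiling (default 200); negative inputs are errors.

## Network construction and pruning

2-way networks hold all C(n,2) pair edges, 3-way networks all C(n,3)
triplet hyperedges. Triplet weights are produced by a streaming generator:
per species pair, the element-wise-minimum vector is formed once and the
triple-minimum terms for all remaining third species come from a single
vectorised reduction, so construction is O(n²) in memory and fast enough
that the 34,220 triples of a 60-genome panel take seconds on one CPU.
Thresholding can be fused into construction (`build_3way(...,
threshold=...)`), which never materialises sub-threshold hyperedges.

Threshold pruning keeps edges with weight **≥** t (the convention is
"remove below the threshold", so a 0.75-exact edge survives t = 0.75 but
not t = 0.76). Best-x pruning keeps, for each node, its x highest-weight
incident edges — a hyperedge kept for any of its three members is kept —
with ties at the x-th rank broken by lexicographic order of the sorted
member labels, so outputs are reproducible. Pruning never touches the node
set: nodes isolated by pruning remain in the data files, and whether a
viewer hides them is the viewer's concern.

The maximum spanning tree converts similarity to distance by w′ = 1 − w
and runs Kruskal (networkx) with edges inserted in lexicographic order so
weight ties resolve deterministically. Disconnected inputs yield a maximum
spanning forest rather than an error. Unions of networks keep 2-way edges
and 3-way hyperedges as distinct objects even over overlapping species;
an edge appearing in both operands must carry the same weight (anything
else is an error, since it signals mixing networks from different
matrices or metrics).

## Enrichment

For each (family, species) cell a one-sided Fisher exact test is computed
on the gene-level 2×2 table [[k, K−k], [n−k, N−K−n+k]] (k = family's genes
in the species, K = family total, n = species total, N = grand total); the
p-value is the hypergeometric upper tail P(X ≥ k). Gene level is the
default because genes are the SF matrix's native unit and enrichment is a
directional question; a presence/absence variant is available
(`level="presence"`). Holm–Bonferroni controls the family-wise error rate
at α = 0.05, by default jointly over all family × species tests; a
per-species correction scope is available. Families significant in more
than one species induce the bipartite shared-enriched-family network;
species with no retained family remain as isolated nodes.

## Topology comparison

For each genus, an edge is *inbound* when all its members (two or three)
belong to the genus and *outbound* for each genus that owns at least one
member while another member lies outside — the all-members rule is the
direct extension of "edges connecting species within genera" to
hyperedges. Genera with no outbound (or no inbound) edges are legitimate,
so ratios are pseudocount-smoothed: (inbound+1)/(outbound+1) and its
reciprocal. Each ratio is ranked across genera within each network
(descending — more modular genera rank first — with average ranks on
ties), and a genus's disagreement scores are the absolute rank differences
between the two networks, one per ratio orientation. Scores are symmetric
in the two networks and bounded by (#genera − 1). The intended comparison
is 2-way best-edge vs 3-way best-edge, but any two networks over the same
species set can be compared.

## Viewer export

Graph viewers only draw pairwise edges, so each hyperedge {u, v, w} is
expanded into an auxiliary *edge-node* of degree exactly 3 linked to its
members and carrying the hyperedge weight; 2-way edges pass through. Edge-
node ids are deterministic ("e:" + sorted members joined by "|") so
repeated exports diff cleanly, and the expansion is invertible
(`collapse_expansion`). Writers: SIF (interaction `tw` for edge-node
links, `pw` for 2-way edges), GraphML with node-kind/genus/weight
attributes, and a flat edge list; a node-attribute TSV accompanies every
graph file. Genus colouring is left to the viewer via the attribute table
(conventional default colour for unannotated nodes: grey). Labels
containing tabs or newlines are rejected at write time; species labels in
the edge-node namespace ("e:" prefix) are rejected at expansion.

## Synthetic data

The generator plants the layered structure real gene-family content
exhibits: a universal core, genus-specific blocks, per-genome private
families, and optional *bridge* blocks present in every species of a
chosen genus pair. Present families carry counts of 1 + Poisson(λ) so the
count-aware indices see non-binary structure. Defaults — 4 genera × 4
species; 80 core, 60 genus, 15 private families; λ = 0.5 — were chosen so
that the networks are strongly genus-modular: cross-genus triplets sit
near S₃ ≈ 0.71, below the 0.76 threshold, while within-genus triplets sit
near 0.90. A bridge block of 40 families lifts bridged cross-genus
triplets to S₃ ≈ 0.77 — above threshold — while every pairwise similarity
remains dominated by the within-genus blocks, so the 2-way best-edge
network stays genus-separated. These arithmetic facts follow directly from
the block sizes (for binary profiles the indices are ratios of block-size
sums) and are what the signal-recovery tests exercise.

Genus blocks accept a separate excess-count mean. The enrichment-recovery
scenario uses λ = 19 (≈ 20 genes per species per family) for genus blocks:
a hypergeometric power calculation shows that at 16 genomes a family
spread evenly over a quarter of the panel needs roughly that expansion
before its per-species counts clear a Holm-corrected 0.05 cutoff, so the
scenario emulates genuinely expanded families — gene-count expansions of
the transposase/sporulation-machinery kind — which are the detectable
class for this test.

What the generator does *not* emulate: phylogenetic signal within genera
(all within-genus species are exchangeable), gene loss/gain gradients,
family-size heavy tails, annotation noise, or correlated family
co-occurrence beyond the planted blocks. Passing the recovery tests
therefore shows the pipeline recovers planted block structure under ideal
conditions; it does not certify behaviour on real pan-genome data with
overlapping, noisy blocks.

## Problem sizes and determinism

The test suite runs the exhaustive Sørensen bound on a 4-family universe
(2,400 admissible triples), 10⁴-draw randomised bound checks, a 200-network
brute-force MST oracle on ≤ 7 nodes, and a 60-species (34,220-triple)
construction check — all on one CPU in well under a minute each. All
randomness flows through explicit seeds (numpy `default_rng`; hypothesis
derandomised), and the CLI produces byte-identical outputs for identical
invocations. TSV/SIF outputs begin with a `#` header recording the tool
version and parameters; GraphML files carry no comment header since
networkx owns that serialisation.
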