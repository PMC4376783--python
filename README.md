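# triadnet

**3-way similarity networks over gene-family content profiles.**

Ordinary similarity networks describe a collection of genomes pairwise: one
node per species, one weighted edge per species pair. That view is blind to
genuinely *ternary* structure — gene content shared across three genomes
that no single pair exhibits strongly. `triadnet` builds weighted 3-uniform
hypergraphs ("3-way networks") in which every edge joins a **triplet** of
species, alongside the usual 2-way networks, and provides the pruning,
enrichment and comparison machinery needed to work with them. It is aimed
at comparative genomicists who have a gene-family count matrix (e.g. from
TribeMCL/OrthoMCL-style clustering) and want to ask which relationships a
pairwise view misses.

## The indices

Input is a **species–family (SF) matrix**: rows = gene families, columns =
species, entry *ij* = number of genes of family *i* in species *j*.

For species with binarised profiles (presence/absence), with Venn-region
counts *a, b, c* (families per species), *ab, ac, bc* (pairwise shared),
*abc* (shared by all three):

- 2-way Sørensen: S₂(A,B) = 2·ab / (a + b)
- 3-way Sørensen: S₃(A,B,C) = (3/2) · (ab + ac + bc − abc) / (a + b + c)

The Czekanowski indices are the count-aware analogues on the raw columns
X, Y, Z:

- C₂(X,Y) = 2·Σᵢ min(Xᵢ,Yᵢ) / Σᵢ (Xᵢ+Yᵢ)
- C₃(X,Y,Z) = (3/2) · Σᵢ [min(Xᵢ,Yᵢ) + min(Xᵢ,Zᵢ) + min(Yᵢ,Zᵢ) − min(Xᵢ,Yᵢ,Zᵢ)] / Σᵢ (Xᵢ+Yᵢ+Zᵢ)

A structural fact drives threshold pruning: **if no family is present in
all three species (abc = 0), both 3-way indices are ≤ 3/4.** Thresholding
a 3-way network at 0.76 therefore keeps only triplets whose weight provably
includes a three-way intersection contribution, not merely two strong
pairs. The test suite verifies this bound exhaustively (Sørensen, 4-family
universe) and by randomised search (Czekanowski).

Also provided: per-node best-x edge pruning, maximum spanning trees (via
w′ = 1 − w inversion), unions of pruned 3-way networks with 2-way MSTs,
gene-family enrichment (one-sided Fisher exact test, Holm–Bonferroni,
bipartite shared-enriched-family networks), a rank-based genus-level
disagreement measure between 2-way and 3-way topologies, degree-3
edge-node expansion for Cytoscape-style viewers (SIF/GraphML), and a
TribeMCL-style reciprocal-E-value pair score.

## Worked example

`triadnet` ships a synthetic SF-matrix generator with genus block
structure (core, genus-specific, private and cross-genus "bridge"
families), so the whole pipeline is runnable without any downloads:

```sh
triadnet simulate --seed 3 --out demo          # 560 families × 16 species, 4 genera
triadnet build3 demo.sf.tsv --metric sorensen --out net3.tsv
triadnet prune net3.tsv --threshold 0.76 --out net3.thr.tsv
triadnet expand net3.thr.tsv --format sif --genus demo.genus.tsv --out net3.sif
```

which reports:

```
wrote demo.sf.tsv (560 families × 16 species) and demo.genus.tsv
wrote net3.tsv: 560 hyperedges over 16 species
threshold: 560 → 16 edges
```

All 16 surviving hyperedges are within-genus triplets of weight 0.9032 —
with no planted cross-genus signal, thresholding at 0.76 recovers exactly
the four genus blocks (4 genera × C(4,3) = 16 triples). Now plant a bridge
block of 40 families shared between the first two genera:

```sh
echo "n_bridge_families=40" > bridge.cfg
triadnet simulate --seed 3 --config bridge.cfg --out bridged
triadnet build3 bridged.sf.tsv --out bnet3.tsv
triadnet prune bnet3.tsv --threshold 0.76 --out bnet3.thr.tsv
```

The thresholded network now keeps 64 hyperedges, 48 of them cross-genus
(e.g. `g01_sp01, g01_sp02, g02_sp01` at weight 0.7692 ≥ 0.76), while the
2-way best-edge network built from the same matrix contains **zero**
cross-genus edges: the two genera look unrelated pairwise, yet the 3-way
network exposes their shared family block. This is precisely the class of
relationship 3-way networks exist to find.

In Python the same analysis reads:

```python
import triadnet as t

m = t.read_sf_matrix("bridged.sf.tsv", "bridged.genus.tsv")
net3 = t.build_3way(m, "sorensen")              # C(16,3) = 560 hyperedges
thr, report = t.threshold_prune(net3, 0.76)     # 560 -> 64
mst = t.maximum_spanning_tree(t.build_2way(m))  # 15-edge backbone
combined = t.union_networks(t.best_x_edges(net3, 2)[0], mst)
graph = t.expand_for_viewer(combined, m.genus_of)
t.write_graph(graph, "combined.graphml", "graphml")
```

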