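"""Similarity network construction and pruning.

A 2-way network holds one weighted edge per species pair; a 3-way network
is a 3-uniform hypergraph holding one weighted hyperedge per species
triplet.  Both are built all-vs-all from an SF matrix with either the
Sørensen (presence/absence) or Czekanowski (count-aware) index, then
sparsified by one of three strategies:

* **threshold** — drop edges with weight < t (default t = 0.76, just above
  the 0.75 ceiling that any triplet with an empty three-way intersection
  cannot exceed, so every surviving triple has a genuine 3-way component);
* **best-x edges** — per node keep its x strongest incident edges and take
  the union over nodes (x = 2 gives the "best and second best edge"
  networks);
* **maximum spanning tree** (2-way only) — the backbone tree of maximum
  total weight, computed as a minimum spanning tree on inverted weights
  w′ = 1 − w.

Unions of a pruned 3-way network with a 2-way MST give the combined
"best of both worlds" view: MST connectivity plus hypergraph modularity.

Triplet weights are produced by a streaming generator so thresholding can
be fused with construction; a fully materialised C(211,3) ≈ 1.5 M-edge
network still fits comfortably in memory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import networkx as nx
import numpy as np

from .sfmatrix import SpeciesFamilyMatrix

__all__ = [
    "WeightedNetwork2",
    "WeightedNetwork3",
    "MixedNetwork",
    "PruneReport",
    "build_2way",
    "build_3way",
    "iter_triplet_weights",
    "threshold_prune",
    "best_x_edges",
    "maximum_spanning_tree",
    "union_networks",
    "write_edgelist",
    "read_edgelist",
]

Metric = Literal["sorensen", "czekanowski"]


def _check_weight(w: float) -> float:
    w = float(w)
    if not (0.0 <= w <= 1.0) or w != w:
        raise ValueError(f"edge weight must lie in [0, 1], got {w}")
    return w


@dataclass
class WeightedNetwork2:
    """Weighted undirected network over species: unordered pairs → weight
    in [0, 1].  Edge keys are stored as sorted label tuples; isolated nodes
    are legitimate members of ``nodes``."""

    nodes: tuple[str, ...] = ()
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    kind = 2

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for key in list(self.edges):
            self.edges[key] = _check_weight(self.edges[key])
            if len(set(key)) != 2:
                raise ValueError(f"self-pair edge {key!r}")
            if tuple(sorted(key)) != key:
                raise ValueError(f"edge key not sorted: {key!r}")
            if any(n not in set(self.nodes) for n in key):
                raise ValueError(f"edge {key!r} references unknown node")

    @staticmethod
    def edge_key(u: str, v: str) -> tuple[str, str]:
        if u == v:
            raise ValueError(f"self-pair ({u!r}, {v!r})")
        return (u, v) if u < v else (v, u)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        key = self.edge_key(u, v)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key!r}")
        self.edges[key] = _check_weight(weight)

    def incident(self, node: str) -> list[tuple[tuple[str, str], float]]:
        return [(k, w) for k, w in self.edges.items() if node in k]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def replace_edges(self, edges: dict[tuple[str, str], float]
                      ) -> "WeightedNetwork2":
        return WeightedNetwork2(self.nodes, dict(edges))


@dataclass
class WeightedNetwork3:
    """3-uniform weighted hypergraph over species: unordered triples of
    distinct species → weight in [0, 1]."""

    nodes: tuple[str, ...] = ()
    edges: dict[tuple[str, str, str], float] = field(default_factory=dict)

    kind = 3

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        node_set = set(self.nodes)
        for key in list(self.edges):
            self.edges[key] = _check_weight(self.edges[key])
            if len(set(key)) != 3:
                raise ValueError(f"hyperedge must join 3 distinct species: {key!r}")
            if tuple(sorted(key)) != key:
                raise ValueError(f"hyperedge key not sorted: {key!r}")
            if any(n not in node_set for n in key):
                raise ValueError(f"hyperedge {key!r} references unknown node")

    @staticmethod
    def edge_key(u: str, v: str, w: str) -> tuple[str, str, str]:
        if len({u, v, w}) != 3:
            raise ValueError(f"hyperedge members must be distinct: {(u, v, w)!r}")
        return tuple(sorted((u, v, w)))  # type: ignore[return-value]

    def add_edge(self, u: str, v: str, w: str, weight: float) -> None:
        key = self.edge_key(u, v, w)
        if key in self.edges:
            raise ValueError(f"duplicate hyperedge {key!r}")
        self.edges[key] = _check_weight(weight)

    def incident(self, node: str) -> list[tuple[tuple[str, str, str], float]]:
        return [(k, w) for k, w in self.edges.items() if node in k]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def replace_edges(self, edges: dict[tuple[str, str, str], float]
                      ) -> "WeightedNetwork3":
        return WeightedNetwork3(self.nodes, dict(edges))


@dataclass
class MixedNetwork:
    """Union container holding 2-way edges and 3-way hyperedges over one
    node universe.  A pair edge and a hyperedge are distinct objects even
    when their species overlap."""

    nodes: tuple[str, ...] = ()
    edges2: dict[tuple[str, str], float] = field(default_factory=dict)
    edges3: dict[tuple[str, str, str], float] = field(default_factory=dict)

    kind = "mixed"

    def __post_init__(self) -> None:
        # validate via the component types
        WeightedNetwork2(self.nodes, dict(self.edges2))
        WeightedNetwork3(self.nodes, dict(self.edges3))
        self.nodes = tuple(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges2) + len(self.edges3)

    def projection2(self) -> WeightedNetwork2:
        """2-way view: pair edges plus, for each hyperedge, its three member
        pairs (hyperedge weight reused; useful for connectivity queries)."""
        proj: dict[tuple[str, str], float] = dict(self.edges2)
        for (u, v, w), weight in self.edges3.items():
            for pair in ((u, v), (u, w), (v, w)):
                proj.setdefault(pair, weight)
        return WeightedNetwork2(self.nodes, proj)


@dataclass(frozen=True)
class PruneReport:
    """Before/after bookkeeping for a pruning operation."""

    edges_before: int
    edges_after: int
    strategy: Literal["threshold", "best_x", "mst"]
    parameters: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        if self.edges_after > self.edges_before:
            raise ValueError("pruning cannot add edges")


# -- construction ---------------------------------------------------------

def _metric_arrays(matrix: SpeciesFamilyMatrix, metric: Metric) -> np.ndarray:
    if metric == "sorensen":
        return matrix.binary().to_numpy(dtype=np.float64)
    if metric == "czekanowski":
        return matrix.counts.to_numpy(dtype=np.float64)
    raise ValueError(f"unknown metric {metric!r}; use 'sorensen' or 'czekanowski'")


def build_2way(matrix: SpeciesFamilyMatrix, metric: Metric = "sorensen"
               ) -> WeightedNetwork2:
    """All-vs-all 2-way similarity network: one edge per species pair,
    weighted by the chosen index on the pair's count columns."""
    if matrix.n_species < 2:
        raise ValueError("need at least 2 species for a 2-way network")
    A = _metric_arrays(matrix, metric)  # families × species
    species = matrix.species_ids
    sums = A.sum(axis=0)
    net = WeightedNetwork2(tuple(species))
    for i, j in itertools.combinations(range(len(species)), 2):
        den = sums[i] + sums[j]
        w = 0.0 if den == 0 else 2.0 * float(np.minimum(A[:, i], A[:, j]).sum()) / den
        net.add_edge(species[i], species[j], w)
    return net


def iter_triplet_weights(matrix: SpeciesFamilyMatrix,
                         metric: Metric = "sorensen",
                         ) -> Iterator[tuple[tuple[str, str, str], float]]:
    """Stream ``(sorted species triple, 3-way index)`` over all C(n,3)
    triplets in lexicographic index order.

    Pairwise min-sums are precomputed (O(n²) memory); per pair (i, j) the
    triple-minimum terms for every k > j come from one matrix product, so
    generation is vectorised while remaining a true generator that a fused
    threshold can consume without materialising the full hyperedge set.
    """
    if matrix.n_species < 3:
        raise ValueError("need at least 3 species for a 3-way network")
    A = _metric_arrays(matrix, metric)
    species = matrix.species_ids
    n = len(species)
    sums = A.sum(axis=0)
    pair_min = np.empty((n, n))
    for i in range(n):
        pair_min[i, i:] = np.minimum(A[:, i:i + 1], A[:, i:]).sum(axis=0)
        pair_min[i:, i] = pair_min[i, i:]
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            m_ij = np.minimum(A[:, i], A[:, j])
            triple_min = np.minimum(m_ij[:, None], A[:, j + 1:]).sum(axis=0)
            num = pair_min[i, j] + pair_min[i, j + 1:] + pair_min[j, j + 1:] \
                - triple_min
            den = sums[i] + sums[j] + sums[j + 1:]
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(den > 0, 1.5 * num / den, 0.0)
            for off, k in enumerate(range(j + 1, n)):
                yield ((species[i], species[j], species[k]),
                       float(min(max(w[off], 0.0), 1.0)))


def build_3way(matrix: SpeciesFamilyMatrix, metric: Metric = "sorensen",
               threshold: float | None = None) -> WeightedNetwork3:
    """All-triplet 3-way similarity network (C(n,3) hyperedges).

    Passing `threshold` fuses threshold pruning with construction: only
    hyperedges with weight ≥ threshold are stored.  Hyperedge keys are the
    triple's member labels in sorted order.
    """
    if threshold is not None and not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    edges: dict[tuple[str, str, str], float] = {}
    for raw_key, w in iter_triplet_weights(matrix, metric):
        if threshold is not None and w < threshold:
            continue
        edges[tuple(sorted(raw_key))] = w  # type: ignore[index]
    return WeightedNetwork3(tuple(matrix.species_ids), edges)


# -- pruning --------------------------------------------------------------

def threshold_prune(network, t: float):
    """Keep exactly the edges with weight ≥ t; the node set (including any
    nodes isolated by pruning) is unchanged.  Works on 2-way, 3-way and
    mixed networks.  Returns ``(pruned network, PruneReport)``."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    before = network.n_edges
    if isinstance(network, MixedNetwork):
        pruned = MixedNetwork(
            network.nodes,
            {k: w for k, w in network.edges2.items() if w >= t},
            {k: w for k, w in network.edges3.items() if w >= t},
        )
    else:
        pruned = network.replace_edges(
            {k: w for k, w in network.edges.items() if w >= t})
    report = PruneReport(before, pruned.n_edges, "threshold", (("t", t),))
    return pruned, report


def best_x_edges(network, x: int):
    """Per-node best-x pruning: for every node keep its x highest-weight
    incident edges (hyperedges count for each member) and return the union
    over nodes.  Ties at the x-th rank are broken by lexicographic order of
    the sorted member labels, so output is deterministic.  Nodes with fewer
    than x incident edges contribute all of them.
    Returns ``(pruned network, PruneReport)``."""
    if x < 1:
        raise ValueError(f"x must be a positive integer, got {x}")
    if isinstance(network, MixedNetwork):
        raise TypeError("best_x_edges operates on a single network kind; "
                        "prune before taking unions")
    incident: dict[str, list[tuple[tuple, float]]] = {n: [] for n in network.nodes}
    for key, w in network.edges.items():
        for member in key:
            incident[member].append((key, w))
    keep: set[tuple] = set()
    for node in network.nodes:
        ranked = sorted(incident[node], key=lambda kw: (-kw[1], kw[0]))
        keep.update(key for key, _ in ranked[:x])
    pruned = network.replace_edges(
        {k: w for k, w in network.edges.items() if k in keep})
    report = PruneReport(network.n_edges, pruned.n_edges, "best_x", (("x", x),))
    return pruned, report


def maximum_spanning_tree(network: WeightedNetwork2) -> WeightedNetwork2:
    """Maximum spanning tree of a 2-way similarity network.

    The similarity network is converted to a distance network by inverting
    each weight, w′ = 1 − w, and a minimum spanning tree is taken (Kruskal).
    Edges are fed to the algorithm in lexicographic label order so weight
    ties resolve deterministically.  A disconnected input yields a maximum
    spanning forest (one tree per component); the node set is preserved.
    """
    if len(network.nodes) < 1:
        raise ValueError("network must have at least one node")
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for (u, v) in sorted(network.edges):
        g.add_edge(u, v, distance=1.0 - network.edges[(u, v)])
    tree_edges = nx.minimum_spanning_edges(g, algorithm="kruskal",
                                           weight="distance", data=False)
    kept = {WeightedNetwork2.edge_key(u, v) for u, v in tree_edges}
    return network.replace_edges(
        {k: w for k, w in network.edges.items() if k in kept})


# -- union ----------------------------------------------------------------

def _merge(dst: dict, src: dict, kind: str) -> None:
    for key, w in src.items():
        if key in dst and dst[key] != w:
            raise ValueError(
                f"conflicting weights for {kind} edge {key!r}: "
                f"{dst[key]} vs {w}")
        dst[key] = w


def union_networks(a, b):
    """Union of two networks over the union of their node sets.

    2-way edges and 3-way hyperedges remain distinct objects even over
    overlapping species.  Identical duplicate edges merge to one; the same
    edge with conflicting weights is an error.  The result is the common
    kind when both inputs are 2-way or both 3-way, and a
    :class:`MixedNetwork` otherwise (the paper-style combination of a 3-way
    best-edge network with a 2-way MST is the motivating case).
    """
    nodes = tuple(dict.fromkeys((*a.nodes, *b.nodes)))

    def parts(net) -> tuple[dict, dict]:
        if isinstance(net, MixedNetwork):
            return dict(net.edges2), dict(net.edges3)
        if isinstance(net, WeightedNetwork2):
            return dict(net.edges), {}
        if isinstance(net, WeightedNetwork3):
            return {}, dict(net.edges)
        raise TypeError(f"not a network: {type(net).__name__}")

    e2: dict = {}
    e3: dict = {}
    for net in (a, b):
        p2, p3 = parts(net)
        _merge(e2, p2, "2-way")
        _merge(e3, p3, "3-way")
    if not e3 and isinstance(a, WeightedNetwork2) and isinstance(b, WeightedNetwork2):
        return WeightedNetwork2(nodes, e2)
    if not e2 and isinstance(a, WeightedNetwork3) and isinstance(b, WeightedNetwork3):
        return WeightedNetwork3(nodes, e3)
    return MixedNetwork(nodes, e2, e3)


# -- edge-list I/O --------------------------------------------------------

def write_edgelist(network, path, header_comment: str | None = None) -> None:
    """Write a network as TSV edge lines with 6-decimal weights.

    2-way lines are ``speciesA<TAB>speciesB<TAB>weight``; 3-way lines carry
    three member columns.  Members are in lexicographic order, lines sorted,
    and isolated nodes recorded in ``# node:`` comments so reading back
    preserves the node universe.
    """
    if isinstance(network, MixedNetwork):
        e2, e3 = network.edges2, network.edges3
    elif isinstance(network, WeightedNetwork2):
        e2, e3 = network.edges, {}
    else:
        e2, e3 = {}, network.edges
    touched = {m for k in (*e2, *e3) for m in k}
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for node in network.nodes:
            if node not in touched:
                fh.write(f"# node: {node}\n")
        for key in sorted(e2):
            fh.write("\t".join(key) + f"\t{e2[key]:.6f}\n")
        for key in sorted(e3):
            fh.write("\t".join(key) + f"\t{e3[key]:.6f}\n")


def read_edgelist(path):
    """Read an edge-list TSV written by :func:`write_edgelist`.

    Returns a :class:`WeightedNetwork2`, :class:`WeightedNetwork3` or
    :class:`MixedNetwork` according to the line shapes found (3 fields =
    pair edge, 4 fields = hyperedge).
    """
    e2: dict = {}
    e3: dict = {}
    isolated: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("# node: "):
                    isolated.append(line[len("# node: "):])
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                e2[WeightedNetwork2.edge_key(fields[0], fields[1])] = float(fields[2])
            elif len(fields) == 4:
                e3[WeightedNetwork3.edge_key(*fields[:3])] = float(fields[3])
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(fields)}")
    touched = [m for k in (*sorted(e2), *sorted(e3)) for m in k]
    nodes = tuple(dict.fromkeys((*touched, *isolated)))
    if e2 and e3:
        return MixedNetwork(nodes, e2, e3)
    if e3:
        return WeightedNetwork3(nodes, e3)
    return WeightedNetwork2(nodes, e2)
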