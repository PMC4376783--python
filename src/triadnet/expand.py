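"""Edge-node expansion of hypergraphs and graph-file export.

Standard graph viewers (Cytoscape and friends) only display edges joining
two nodes, so a 3-way network is transformed before export: every
hyperedge {u, v, w} becomes an auxiliary *edge-node* of degree exactly 3,
linked to its three member species and carrying the hyperedge weight.
2-way edges pass through unchanged.  Edge-node identifiers are
deterministic ("e:" + the sorted member labels joined by "|"), node kinds
are tagged, and the expansion is invertible: :func:`collapse_expansion`
recovers the original network exactly.

Writers cover Cytoscape SIF (interaction type ``tw`` for edge-node links,
``pw`` for plain 2-way edges), GraphML (with node-kind, genus and weight
attributes) and a plain edge-list TSV; a node-attribute TSV is written
alongside every graph file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx

from .networks import MixedNetwork, WeightedNetwork2, WeightedNetwork3

__all__ = ["ExpandedGraph", "expand_for_viewer", "collapse_expansion",
           "write_graph", "EDGE_NODE_PREFIX", "DEFAULT_GENUS_COLOR"]

EDGE_NODE_PREFIX = "e:"
DEFAULT_GENUS_COLOR = "grey"


@dataclass
class ExpandedGraph:
    """Viewer-compatible plain graph produced by edge-node expansion.

    ``graph`` is an undirected networkx graph whose nodes carry a ``kind``
    attribute ("species" or "edge-node"), optionally a ``genus``, and — for
    edge-nodes — the originating hyperedge's ``weight``.  Links carry a
    ``kind`` ("tw" for hyperedge-member links, "pw" for 2-way edges) and a
    ``weight``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def species_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "species"]

    @property
    def edge_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "edge-node"]

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        for en in self.edge_nodes:
            if self.graph.degree(en) != 3:
                raise ValueError(
                    f"edge-node {en!r} has degree {self.graph.degree(en)}, "
                    "expected exactly 3")


def _edge_node_id(key: tuple[str, str, str]) -> str:
    return EDGE_NODE_PREFIX + "|".join(sorted(key))


def expand_for_viewer(network, genus_of: Mapping[str, str] | None = None
                      ) -> ExpandedGraph:
    """Expand a 3-way (or mixed, or plain 2-way) network for display.

    Each hyperedge becomes a degree-3 edge-node; 2-way edges pass through.
    An optional genus annotation is attached to species nodes (edge-nodes
    get none; the conventional viewer colour for unannotated nodes is
    grey).
    """
    if isinstance(network, MixedNetwork):
        e2, e3 = network.edges2, network.edges3
    elif isinstance(network, WeightedNetwork2):
        e2, e3 = network.edges, {}
    elif isinstance(network, WeightedNetwork3):
        e2, e3 = {}, network.edges
    else:
        raise TypeError(f"not a network: {type(network).__name__}")
    g = nx.Graph()
    for node in network.nodes:
        if node.startswith(EDGE_NODE_PREFIX):
            raise ValueError(
                f"species label {node!r} collides with the edge-node "
                f"namespace ({EDGE_NODE_PREFIX!r} prefix)")
        attrs = {"kind": "species"}
        if genus_of is not None and node in genus_of:
            attrs["genus"] = genus_of[node]
        g.add_node(node, **attrs)
    for (u, v), w in sorted(e2.items()):
        g.add_edge(u, v, kind="pw", weight=w)
    for key in sorted(e3):
        en = _edge_node_id(key)
        g.add_node(en, kind="edge-node", weight=e3[key])
        for member in key:
            g.add_edge(en, member, kind="tw", weight=e3[key])
    out = ExpandedGraph(g)
    out.validate()
    return out


def collapse_expansion(expanded: ExpandedGraph):
    """Invert :func:`expand_for_viewer`: rebuild the network whose
    expansion this is.  Returns a :class:`MixedNetwork` (either component
    may be empty)."""
    g = expanded.graph
    nodes = tuple(sorted(expanded.species_nodes))
    e2: dict = {}
    e3: dict = {}
    for en in expanded.edge_nodes:
        members = tuple(sorted(g.neighbors(en)))
        if len(members) != 3:
            raise ValueError(f"edge-node {en!r} does not have 3 members")
        e3[members] = g.nodes[en]["weight"]
    for u, v, d in g.edges(data=True):
        if d["kind"] == "pw":
            e2[WeightedNetwork2.edge_key(u, v)] = d["weight"]
    return MixedNetwork(nodes, e2, e3)


def _attr_path(path: Path) -> Path:
    return path.with_name(path.name + ".nodes.tsv")


def _check_labels(g: nx.Graph) -> None:
    for n in g.nodes:
        if "\t" in n or "\n" in n:
            raise ValueError(f"node label contains tab/newline: {n!r}")


def write_graph(obj, path: str | Path,
                fmt: Literal["sif", "graphml", "edgelist"] = "sif",
                header_comment: str | None = None) -> None:
    """Write an :class:`ExpandedGraph` (or a plain 2-way network, expanded
    on the fly) to `path` in the requested format, plus a node-attribute
    TSV (columns: node, kind, genus, weight) at ``<path>.nodes.tsv``.

    SIF lines are ``source<TAB>interaction<TAB>target`` with interaction
    ``tw`` for edge-node links and ``pw`` for 2-way edges; GraphML carries
    the node and link attributes natively (no comment header — the XML
    serialisation is networkx's).
    """
    if isinstance(obj, (WeightedNetwork2, WeightedNetwork3, MixedNetwork)):
        obj = expand_for_viewer(obj)
    if not isinstance(obj, ExpandedGraph):
        raise TypeError(f"cannot export {type(obj).__name__}")
    g = obj.graph
    _check_labels(g)
    path = Path(path)

    def header_lines():
        if header_comment:
            return [f"# {line}\n" for line in header_comment.splitlines()]
        return []

    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            fh.writelines(header_lines())
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{d['kind']}\t{v}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")  # SIF convention for isolated nodes
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.writelines(header_lines())
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['kind']}\t{d['weight']:.6f}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use sif, graphml or edgelist")

    with open(_attr_path(path), "w", encoding="utf-8") as fh:
        fh.writelines(header_lines())
        fh.write("node\tkind\tgenus\tweight\n")
        for n in sorted(g.nodes):
            d = g.nodes[n]
            genus = d.get("genus", "")
            weight = f"{d['weight']:.6f}" if "weight" in d else ""
            fh.write(f"{n}\t{d['kind']}\t{genus}\t{weight}\n")
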