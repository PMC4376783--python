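"""Rank-based disagreement between 2-way and 3-way network topologies.

For each genus, edges of a network are classified as *inbound* (every
member species belongs to the genus) or *outbound* (at least one member
inside and at least one outside); edges touching a genus in neither role do
not count for it.  The smoothed ratio (inbound+1)/(outbound+1) summarises
how modular the genus is in that network.  Ranking these ratios within a
2-way network and within a 3-way network and taking per-genus absolute
rank differences yields the disagreement scores: large scores flag genera
whose local topology the two network models describe differently — the
places where triplet similarity adds information beyond pairwise
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy.stats import rankdata

from .networks import MixedNetwork, WeightedNetwork2, WeightedNetwork3

__all__ = ["GenusEdgeStats", "DisagreementScore",
           "genus_edge_stats", "disagreement_scores"]


@dataclass(frozen=True)
class GenusEdgeStats:
    """Inbound/outbound edge counts and smoothed ratios for one genus."""

    genus: str
    inbound: int
    outbound: int
    ratio_io: float  # (inbound + 1) / (outbound + 1)
    ratio_oi: float  # (outbound + 1) / (inbound + 1)

    def __post_init__(self) -> None:
        if self.inbound < 0 or self.outbound < 0:
            raise ValueError("edge counts must be non-negative")
        if self.ratio_io <= 0 or self.ratio_oi <= 0:
            raise ValueError("smoothed ratios must be positive")


@dataclass(frozen=True)
class DisagreementScore:
    """Absolute rank shifts of one genus's ratios between two networks.

    ``d_oi`` is the shift for the inbound/outbound ratio, ``d_io`` for the
    reciprocal ratio; both are bounded by (number of genera − 1).
    """

    genus: str
    d_oi: float
    d_io: float

    def __post_init__(self) -> None:
        if self.d_oi < 0 or self.d_io < 0:
            raise ValueError("disagreement scores are non-negative")


def _edge_keys(network):
    if isinstance(network, MixedNetwork):
        return [*network.edges2, *network.edges3]
    if isinstance(network, (WeightedNetwork2, WeightedNetwork3)):
        return list(network.edges)
    raise TypeError(f"not a network: {type(network).__name__}")


def genus_edge_stats(network, genus_of: Mapping[str, str]
                     ) -> list[GenusEdgeStats]:
    """Per-genus inbound/outbound edge counts for a 2- or 3-way network.

    An edge (pair or hyperedge) is inbound for a genus when *all* its
    members belong to that genus, and outbound for every genus that owns at
    least one member while at least one member lies outside it.  The
    pseudocount-smoothed ratios keep ranks well-defined for genera with no
    outbound (or no inbound) edges.  Stats are returned for every genus
    represented among the network's nodes, sorted by genus label.
    """
    unmapped = [n for n in network.nodes if n not in genus_of]
    if unmapped:
        raise ValueError(f"species without genus annotation: {unmapped!r}")
    genera = sorted({genus_of[n] for n in network.nodes})
    inbound = {g: 0 for g in genera}
    outbound = {g: 0 for g in genera}
    for key in _edge_keys(network):
        member_genera = {genus_of[m] for m in key}
        if len(member_genera) == 1:
            inbound[next(iter(member_genera))] += 1
        else:
            for g in member_genera:
                outbound[g] += 1
    return [GenusEdgeStats(g, inbound[g], outbound[g],
                           (inbound[g] + 1) / (outbound[g] + 1),
                           (outbound[g] + 1) / (inbound[g] + 1))
            for g in genera]


def disagreement_scores(net2, net3, genus_of: Mapping[str, str]
                        ) -> list[DisagreementScore]:
    """Disagreement between genus-level topology of two networks.

    Each genus's inbound/outbound ratio is ranked within `net2` and within
    `net3` (descending; ties get average ranks) and the absolute rank
    difference is its ``d_oi`` score; ranking the reciprocal ratios gives
    ``d_io``.  Conventionally `net2` is the 2-way best-edge network and
    `net3` the 3-way best-edge network, but any pair over the same species
    set may be compared.
    """
    stats2 = genus_edge_stats(net2, genus_of)
    stats3 = genus_edge_stats(net3, genus_of)
    g2 = [s.genus for s in stats2]
    g3 = [s.genus for s in stats3]
    if g2 != g3:
        raise ValueError(f"networks cover different genera: {g2!r} vs {g3!r}")
    if len(g2) < 2:
        raise ValueError("ranking needs at least 2 genera")

    def ranks(values):  # descending, average ranks for ties
        return rankdata([-v for v in values], method="average")

    r2_io = ranks([s.ratio_io for s in stats2])
    r3_io = ranks([s.ratio_io for s in stats3])
    r2_oi = ranks([s.ratio_oi for s in stats2])
    r3_oi = ranks([s.ratio_oi for s in stats3])
    return [DisagreementScore(g, abs(float(a - b)), abs(float(c - d)))
            for g, a, b, c, d in zip(g2, r2_io, r3_io, r2_oi, r3_oi)]
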