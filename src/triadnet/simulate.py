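"""Synthetic SF matrices with controlled genus block structure.

Real bacterial gene-family content has a layered structure: a core shared
by everything, genus-specific blocks, per-genome private families, and —
the interesting case — families shared across a *pair* of genera (think of
the sporulation machinery common to Clostridium and Bacillus).  The
generator plants exactly these layers:

* ``n_core_families`` present in every species;
* ``n_genus_families`` per genus, present in that genus's species only;
* ``n_private_families`` per species, present in that one species;
* ``n_bridge_families`` per configured genus pair, present in every
  species of both genera — a block that creates genuine three-way signal
  between the genera while leaving every pairwise similarity dominated by
  the within-genus blocks.

A present family's gene count is 1 plus a Poisson-distributed excess, so
Czekanowski (count-aware) metrics see non-binary structure; genus blocks
can take a larger excess mean to emulate expanded families, the kind that
per-species enrichment tests can actually detect.  All randomness flows
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .sfmatrix import SpeciesFamilyMatrix

__all__ = ["SyntheticConfig", "generate_sf"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic SF-matrix generator.

    Default block sizes (4 genera × 4 species; 80 core, 60 genus, 15
    private families; excess count mean 0.5) give strongly genus-modular
    networks in which cross-genus triplets fall below the 0.76 pruning
    threshold unless a bridge block is planted; a bridge of 40 families
    lifts bridged cross-genus triplets just above it, mirroring the kind of
    two-genus linkage 3-way networks are designed to expose.
    """

    n_genera: int = 4
    species_per_genus: int = 4
    n_core_families: int = 80
    n_genus_families: int = 60
    n_private_families: int = 15
    n_bridge_families: int = 0
    bridge_pairs: tuple[tuple[int, int], ...] = ()
    extra_count_mean: float = 0.5
    genus_extra_count_mean: float | None = None
    bridge_extra_count_mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_genera", "species_per_genus", "n_core_families",
                  "n_genus_families", "n_private_families",
                  "n_bridge_families"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f} must be a non-negative integer, got {v!r}")
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("need at least one genus and one species per genus")
        for m in (self.extra_count_mean, self.genus_extra_count_mean,
                  self.bridge_extra_count_mean):
            if m is not None and m < 0:
                raise ValueError("excess count means must be non-negative")
        for pair in self.bridge_pairs:
            i, j = pair
            if i == j or not (0 <= i < self.n_genera) or not (0 <= j < self.n_genera):
                raise ValueError(f"invalid bridge genus pair {pair!r}")
        if self.n_bridge_families > 0 and not self.bridge_pairs:
            if self.n_genera < 2:
                raise ValueError("bridge families need at least two genera")
            object.__setattr__(self, "bridge_pairs", ((0, 1),))


def _counts(rng: np.random.Generator, shape, extra_mean: float) -> np.ndarray:
    """Gene counts for present families: 1 + Poisson(extra_mean)."""
    return 1 + rng.poisson(extra_mean, size=shape)


def generate_sf(config: SyntheticConfig) -> SpeciesFamilyMatrix:
    """Generate a synthetic SF matrix (genus annotation included).

    Deterministic given ``config.seed``; family and species labels encode
    their block of origin (core / genus / private / bridge) so tests can
    identify planted structure.
    """
    rng = np.random.default_rng(config.seed)
    genera = [f"g{i + 1:02d}" for i in range(config.n_genera)]
    species: list[str] = []
    genus_of: dict[str, str] = {}
    for g in genera:
        for j in range(config.species_per_genus):
            sp = f"{g}_sp{j + 1:02d}"
            species.append(sp)
            genus_of[sp] = g

    blocks: list[tuple[str, list[str]]] = []  # (family id, carrier species)
    for i in range(config.n_core_families):
        blocks.append((f"core{i + 1:04d}", species))
    for gi, g in enumerate(genera):
        members = [sp for sp in species if genus_of[sp] == g]
        for i in range(config.n_genus_families):
            blocks.append((f"{g}_fam{i + 1:04d}", members))
    for sp in species:
        for i in range(config.n_private_families):
            blocks.append((f"{sp}_priv{i + 1:02d}", [sp]))
    for (ga, gb) in config.bridge_pairs:
        members = [sp for sp in species
                   if genus_of[sp] in (genera[ga], genera[gb])]
        for i in range(config.n_bridge_families):
            blocks.append((f"bridge_{genera[ga]}_{genera[gb]}_{i + 1:04d}",
                           members))

    col_index = {sp: j for j, sp in enumerate(species)}
    counts = np.zeros((len(blocks), len(species)), dtype=np.int64)
    for row, (fam, carriers) in enumerate(blocks):
        if fam.startswith("bridge_"):
            mean = (config.bridge_extra_count_mean
                    if config.bridge_extra_count_mean is not None
                    else config.extra_count_mean)
        elif "_fam" in fam:
            mean = (config.genus_extra_count_mean
                    if config.genus_extra_count_mean is not None
                    else config.extra_count_mean)
        else:
            mean = config.extra_count_mean
        cols = [col_index[sp] for sp in carriers]
        counts[row, cols] = _counts(rng, len(cols), mean)

    df = pd.DataFrame(counts, index=[fam for fam, _ in blocks],
                      columns=species)
    return SpeciesFamilyMatrix(df, genus_of)
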