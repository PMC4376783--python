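"""Species–family (SF) matrix data model and tabular I/O.

The SF matrix is the central input of the package: a non-negative integer
count matrix whose rows are gene families, whose columns are species
(genomes), and whose entry (i, j) is the number of genes of family *i*
carried by species *j*.  Such matrices are typically produced upstream by
clustering an all-vs-all protein similarity network into families (e.g.
with TribeMCL) and counting members per genome; here they are read from a
plain TSV or produced by :mod:`triadnet.simulate`.

All similarity and enrichment computations in the package consume this
object, either through its raw counts (Czekanowski-type metrics, Fisher
enrichment) or through its binarised presence/absence form (Sørensen-type
metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesFamilyMatrix",
    "BinaryProfile",
    "VennCounts3",
    "read_sf_matrix",
    "write_sf_matrix",
    "read_genus_map",
    "write_genus_map",
    "binarize",
    "venn_counts",
]


class BinaryProfile(NamedTuple):
    """Presence/absence profile of one species over the family universe.

    ``bits[i]`` is 1 exactly when the species carries at least one gene of
    family *i*, and 0 otherwise.
    """

    species_id: str
    bits: np.ndarray


@dataclass(frozen=True)
class VennCounts3:
    """Seven-region occupancy counts of a three-species Venn diagram.

    ``a``/``b``/``c`` are total family counts per species, ``ab``/``ac``/``bc``
    pairwise shared counts, ``abc`` the triple intersection, and
    ``a_only``/``b_only``/``c_only`` the families private to one species
    within the triple.
    """

    a: int
    b: int
    c: int
    ab: int
    ac: int
    bc: int
    abc: int
    a_only: int
    b_only: int
    c_only: int

    def __post_init__(self) -> None:
        if self.abc > min(self.ab, self.ac, self.bc):
            raise ValueError("abc cannot exceed any pairwise intersection")
        if self.ab > min(self.a, self.b) or self.ac > min(self.a, self.c) \
                or self.bc > min(self.b, self.c):
            raise ValueError("pairwise intersection exceeds a species total")
        # region decomposition, e.g. a = ā + (ab−abc) + (ac−abc) + abc
        if self.a != self.a_only + (self.ab - self.abc) + (self.ac - self.abc) + self.abc:
            raise ValueError("region decomposition violated for species A")
        if self.b != self.b_only + (self.ab - self.abc) + (self.bc - self.abc) + self.abc:
            raise ValueError("region decomposition violated for species B")
        if self.c != self.c_only + (self.ac - self.abc) + (self.bc - self.abc) + self.abc:
            raise ValueError("region decomposition violated for species C")


@dataclass
class SpeciesFamilyMatrix:
    """Gene-family count matrix with labelled rows (families) and columns
    (species), plus an optional species → genus annotation.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer gene counts; index = family ids,
        columns = species ids.  Orientation is fixed: families in rows.
    genus_of
        Optional mapping from every species id to a genus label.  Operations
        that need genus structure (topology comparison, genus-aware exports)
        fail fast when it is absent.
    """

    counts: pd.DataFrame
    genus_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate family ids: {list(dups)!r}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate species ids: {list(dups)!r}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            _raise_on_bad_cells(self.counts)
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at family {self.counts.index[i]!r}, "
                f"species {self.counts.columns[j]!r}"
            )
        if self.genus_of is not None:
            missing = [s for s in self.species_ids if s not in self.genus_of]
            if missing:
                raise ValueError(f"genus map does not cover species: {missing!r}")
            extra = [s for s in self.genus_of if s not in set(self.species_ids)]
            if extra:
                raise ValueError(f"genus map lists unknown species: {extra!r}")

    # -- basic views ------------------------------------------------------

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_families(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def column(self, species_id: str) -> np.ndarray:
        """Raw count vector of one species over all families."""
        return self.counts[species_id].to_numpy()

    def binary(self) -> pd.DataFrame:
        """Presence/absence (0/1) view of the counts."""
        return (self.counts >= 1).astype(np.int8)

    def require_genus(self) -> dict[str, str]:
        if self.genus_of is None:
            raise ValueError(
                "this operation needs a species→genus annotation; load one "
                "with read_genus_map() or pass genus_of="
            )
        return self.genus_of

    def select_species(self, species: Sequence[str]) -> "SpeciesFamilyMatrix":
        """Sub-matrix over the given species; families are retained even if
        absent from every selected species (all-zero rows contribute
        nothing to any index)."""
        genus = None
        if self.genus_of is not None:
            genus = {s: self.genus_of[s] for s in species}
        return SpeciesFamilyMatrix(self.counts[list(species)].copy(), genus)


def _raise_on_bad_cells(df: pd.DataFrame) -> None:
    """Identify the first non-integer cell and raise a parse error naming it."""
    arr = df.to_numpy()
    if np.issubdtype(arr.dtype, np.floating):
        bad = ~np.isfinite(arr) | (arr != np.floor(arr))
    else:  # object dtype: strings or mixed
        def _ok(v: object) -> bool:
            try:
                return float(v) == int(float(v))
            except (TypeError, ValueError):
                return False

        bad = ~np.vectorize(_ok, otypes=[bool])(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer cell {arr[i, j]!r} at family {df.index[i]!r}, "
            f"species {df.columns[j]!r}"
        )


# -- I/O ------------------------------------------------------------------

def read_sf_matrix(path: str | Path, genus_path: str | Path | None = None,
                   ) -> SpeciesFamilyMatrix:
    """Read an SF matrix from TSV (families in rows, species in columns).

    The first header cell is ignored; remaining header cells are species
    ids; the first column holds family ids; all other cells must be
    non-negative integers.  Lines starting with ``#`` are skipped.  Row and
    column order are preserved exactly as in the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=object)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _raise_on_bad_cells(df)
    counts = df.astype(np.int64)
    genus = read_genus_map(genus_path) if genus_path is not None else None
    return SpeciesFamilyMatrix(counts, genus)


def write_sf_matrix(matrix: SpeciesFamilyMatrix, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write the SF matrix in the same TSV dialect :func:`read_sf_matrix`
    reads; round-trips are lossless for labels and counts."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("family\t" + "\t".join(matrix.species_ids) + "\n")
        matrix.counts.to_csv(fh, sep="\t", header=False)


def read_genus_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``species<TAB>genus`` TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["species", "genus"]:
        raise ValueError(
            f"genus map must have header 'species<TAB>genus', got {list(df.columns)!r}"
        )
    if df["species" if "species" in df.columns else df.columns[0]].duplicated().any():
        raise ValueError("duplicate species in genus map")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_genus_map(genus_of: Mapping[str, str], path: str | Path,
                    header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("species\tgenus\n")
        for sp, g in genus_of.items():
            fh.write(f"{sp}\t{g}\n")


# -- binarisation and Venn regions ---------------------------------------

def binarize(matrix: SpeciesFamilyMatrix) -> list[BinaryProfile]:
    """One presence/absence profile per species: bit i = 1 iff count ≥ 1."""
    b = matrix.binary()
    return [BinaryProfile(sp, b[sp].to_numpy()) for sp in matrix.species_ids]


def venn_counts(x: BinaryProfile | np.ndarray,
                y: BinaryProfile | np.ndarray,
                z: BinaryProfile | np.ndarray) -> VennCounts3:
    """Occupancy counts of the seven Venn regions for a species triplet.

    Accepts :class:`BinaryProfile` objects or raw 0/1 vectors over the same
    family universe.  Symmetric up to permuting the roles A/B/C.
    """
    xb, yb, zb = (np.asarray(v.bits if isinstance(v, BinaryProfile) else v)
                  for v in (x, y, z))
    if not (xb.shape == yb.shape == zb.shape):
        raise ValueError(
            f"profiles cover different family universes: "
            f"{xb.shape} vs {yb.shape} vs {zb.shape}"
        )
    xb, yb, zb = (v.astype(bool) for v in (xb, yb, zb))
    a, b, c = int(xb.sum()), int(yb.sum()), int(zb.sum())
    ab = int((xb & yb).sum())
    ac = int((xb & zb).sum())
    bc = int((yb & zb).sum())
    abc = int((xb & yb & zb).sum())
    return VennCounts3(
        a=a, b=b, c=c, ab=ab, ac=ac, bc=bc, abc=abc,
        a_only=int((xb & ~yb & ~zb).sum()),
        b_only=int((yb & ~xb & ~zb).sum()),
        c_only=int((zb & ~xb & ~yb).sum()),
    )
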