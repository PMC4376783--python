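"""Pairwise and triplet similarity indices over gene-content vectors.

Two families of indices are provided, each in a 2-way (pair) and a 3-way
(triplet) form:

* **Sørensen** — presence/absence overlap.  For two species with ``a`` and
  ``b`` families and ``ab`` shared, ``S2 = 2·ab/(a+b)``.  The 3-way form is

      S3(A,B,C) = (3/2) · (ab + ac + bc − abc) / (a + b + c)

  on the Venn-region counts of the triplet.

* **Czekanowski** — the quantitative (count-aware) analogue, replacing set
  intersections with sums of element-wise minima of the raw count vectors:
  ``C2 = 2·Σmin(x,y)/Σ(x+y)`` and

      C3(X,Y,Z) = (3/2) · Σ[min(x,y)+min(x,z)+min(y,z)−min(x,y,z)] / Σ(x+y+z).

Both 3-way indices lie in [0, 1], are invariant under permuting their three
arguments, and reduce to their 2-way counterpart's behaviour on binary
inputs (Czekanowski ≡ Sørensen there).  A key structural fact used for
threshold pruning: whenever the triple intersection is empty (no family
shared by all three species), both 3-way indices are at most 3/4, so any
threshold above 0.75 retains only triplets with a genuine three-way
component.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "sorensen2",
    "sorensen3",
    "czekanowski2",
    "czekanowski3",
    "tribemcl_pair_score",
]


def _as_vectors(*vecs: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(v) for v in vecs]
    n = out[0].shape
    for v in out[1:]:
        if v.shape != n:
            raise ValueError(f"length mismatch: {n} vs {v.shape}")
    for v in out:
        if v.size and v.min() < 0:
            raise ValueError("count vectors must be non-negative")
    return out


def _binarize(v: np.ndarray) -> np.ndarray:
    return (v >= 1).astype(np.float64)


def sorensen2(x, y) -> float:
    """2-way Sørensen index of two count vectors (binarised internally).

    Returns ``2·Σmin(x_B,y_B) / Σ(x_B+y_B)``; defined as 0 when both
    profiles are empty (empty genomes share nothing, and downstream pruning
    treats 0 as no-edge).
    """
    x, y = _as_vectors(x, y)
    xb, yb = _binarize(x), _binarize(y)
    den = float(xb.sum() + yb.sum())
    if den == 0.0:
        return 0.0
    return 2.0 * float(np.minimum(xb, yb).sum()) / den


def sorensen3(x, y, z) -> float:
    """3-way Sørensen index of three count vectors (binarised internally).

    Equals ``(3/2)·(ab+ac+bc−abc)/(a+b+c)`` on the triplet's Venn counts;
    permutation-invariant; 0 when all three profiles are empty.
    """
    x, y, z = _as_vectors(x, y, z)
    xb, yb, zb = _binarize(x), _binarize(y), _binarize(z)
    den = float(xb.sum() + yb.sum() + zb.sum())
    if den == 0.0:
        return 0.0
    num = float(
        np.minimum(xb, yb).sum()
        + np.minimum(xb, zb).sum()
        + np.minimum(yb, zb).sum()
        - np.minimum(np.minimum(xb, yb), zb).sum()
    )
    return 1.5 * num / den


def czekanowski2(x, y) -> float:
    """2-way Czekanowski index: ``2·Σmin(x,y)/Σ(x+y)`` on raw counts.

    Coincides with :func:`sorensen2` when both vectors are binary.
    """
    x, y = _as_vectors(x, y)
    den = float(x.sum() + y.sum())
    if den == 0.0:
        return 0.0
    return 2.0 * float(np.minimum(x, y).sum()) / den


def czekanowski3(x, y, z) -> float:
    """3-way Czekanowski index on raw counts; permutation-invariant and
    equal to :func:`sorensen3` on binary inputs."""
    x, y, z = _as_vectors(x, y, z)
    den = float(x.sum() + y.sum() + z.sum())
    if den == 0.0:
        return 0.0
    num = float(
        np.minimum(x, y).sum()
        + np.minimum(x, z).sum()
        + np.minimum(y, z).sum()
        - np.minimum(np.minimum(x, y), z).sum()
    )
    return 1.5 * num / den


def tribemcl_pair_score(e_ab: float, e_ba: float, *,
                        ceiling: float = 200.0) -> float:
    """Similarity score of a gene pair from its two reciprocal BLAST
    E-values, TribeMCL-style: the negated base-10 logarithm of the mean
    E-value, ``−log10((E_ab + E_ba)/2)``.

    E-values must be ≤ 1 in practice but any positive value is accepted
    (values above 1 give a negative score).  Aligners report underflowed
    E-values as exactly 0; those are clamped at `ceiling` (default 200)
    rather than rejected, so only negative inputs raise.
    """
    for name, e in (("e_ab", e_ab), ("e_ba", e_ba)):
        if e < 0:
            raise ValueError(f"{name} must be non-negative, got {e}")
    mean = (e_ab + e_ba) / 2.0
    if mean == 0.0:
        return float(ceiling)
    return min(float(ceiling), -math.log10(mean))
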