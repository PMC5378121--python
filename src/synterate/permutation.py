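"""Signed permutations of gene labels.

A signed permutation is the common currency of genome-rearrangement
analysis: genome A's shared genes are numbered 1..n along the replicon
(strand taken as +), and genome B is written as the sequence of those
labels in B's order, each negated when the two copies lie on opposite
strands.  Replicons may be circular (bacterial chromosomes) or linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SignedPermutation"]


@dataclass(frozen=True)
class SignedPermutation:
    """An ordering of signed, nonzero gene labels 1..n.

    Parameters
    ----------
    elements :
        Sequence of signed integers whose magnitudes are exactly
        ``{1, ..., n}``, each occurring once.  Sign encodes strand
        agreement relative to the reference genome.
    circular :
        Whether the replicon wraps around (default True: bacterial
        chromosomes are circular).
    """

    elements: tuple[int, ...]
    circular: bool = True

    def __init__(self, elements: Iterable[int], circular: bool = True):
        elems = tuple(int(e) for e in elements)
        n = len(elems)
        if n == 0:
            raise ValueError("permutation must be nonempty")
        mags = sorted(abs(e) for e in elems)
        if mags != list(range(1, n + 1)):
            raise ValueError(
                "element magnitudes must be exactly {1..n}, each once "
                f"(got {mags[:10]}...)" if n > 10 else
                f"element magnitudes must be exactly {{1..n}}, each once (got {mags})"
            )
        object.__setattr__(self, "elements", elems)
        object.__setattr__(self, "circular", bool(circular))

    # -- basic container behaviour ------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i):
        return self.elements[i]

    def to_array(self) -> np.ndarray:
        return np.asarray(self.elements, dtype=np.int64)

    # -- constructors --------------------------------------------------
    @classmethod
    def identity(cls, n: int, circular: bool = True) -> "SignedPermutation":
        return cls(range(1, n + 1), circular=circular)

    # -- elementary operations -----------------------------------------
    def reverse_segment(self, i: int, j: int) -> "SignedPermutation":
        """Return a copy with positions ``i..j`` (inclusive) reversed and
        sign-flipped — a single inversion event."""
        if not (0 <= i <= j < len(self)):
            raise IndexError(f"segment [{i}, {j}] out of range for n={len(self)}")
        e = list(self.elements)
        e[i : j + 1] = [-x for x in reversed(e[i : j + 1])]
        return SignedPermutation(e, circular=self.circular)

    def flip(self) -> "SignedPermutation":
        """Reverse and negate the whole sequence (reading the replicon
        from the other strand); a no-op for distance purposes."""
        return SignedPermutation([-x for x in reversed(self.elements)],
                                 circular=self.circular)

    def rotate(self, k: int) -> "SignedPermutation":
        """Rotate a circular permutation left by ``k`` positions."""
        if not self.circular:
            raise ValueError("cannot rotate a linear permutation")
        k %= len(self)
        return SignedPermutation(self.elements[k:] + self.elements[:k],
                                 circular=True)

    def canonical_linear(self) -> "SignedPermutation":
        """Canonicalize a circular permutation to an equivalent linear one.

        The circle is cut at gene 1 oriented +: rotate so the element of
        magnitude 1 leads, flipping the whole permutation first if that
        element is −1, then drop it and renumber the remaining labels
        down by one.  Reversal distance over the circle equals the linear
        distance of this n−1 element permutation.
        """
        if not self.circular:
            return self
        perm = self
        pos = next(i for i, e in enumerate(perm.elements) if abs(e) == 1)
        if perm.elements[pos] < 0:
            perm = perm.flip()
            pos = next(i for i, e in enumerate(perm.elements) if abs(e) == 1)
        perm = perm.rotate(pos)
        rest = [e - 1 if e > 0 else e + 1 for e in perm.elements[1:]]
        if not rest:  # single-gene circle: trivially sorted
            return SignedPermutation([1], circular=False)
        return SignedPermutation(rest, circular=False)

    # -- adjacency structure -------------------------------------------
    def adjacency_pairs(self) -> set[frozenset[int]]:
        """Unordered, orientation-insensitive neighbour pairs of labels.

        For circular permutations the wrap-around pair is included.
        """
        labels = [abs(e) for e in self.elements]
        n = len(labels)
        pairs = {frozenset((labels[i], labels[i + 1])) for i in range(n - 1)}
        if self.circular and n > 1:
            pairs.add(frozenset((labels[-1], labels[0])))
        return pairs

    def is_identity(self) -> bool:
        return all(e == i + 1 for i, e in enumerate(self.elements))
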