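"""Exact repeat pairs, repeat significance lengths, and MUMs.

Repeated sequences are substrates for ectopic recombination and hence
potential drivers of genome rearrangement.  This module detects all
maximal exact repeat pairs (direct and inverted) above a length cutoff
— either given directly or derived from a Karlin–Ost-style criterion
for the shortest repeat unexpected by chance in a random genome of the
same length and GC content — plus maximal unique matches (MUMs)
between two genomes for dot-plot alignments, and the fraction of a
genome covered by repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RepeatPair",
    "Mum",
    "find_exact_repeats",
    "significant_repeat_length",
    "repeat_coverage",
    "find_mums",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class RepeatPair:
    """Two exact copies (or reverse-complement copies) within one genome."""

    pos1: int
    pos2: int
    length: int
    orientation: str  # "direct" | "inverted"

    def __post_init__(self):
        if self.pos1 >= self.pos2:
            raise ValueError("pos1 must be < pos2")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be 'direct' or 'inverted'")

    def intervals(self) -> list[tuple[int, int]]:
        return [(self.pos1, self.pos1 + self.length),
                (self.pos2, self.pos2 + self.length)]


@dataclass(frozen=True)
class Mum:
    """A maximal match occurring exactly once in each of two genomes."""

    ref_pos: int
    qry_pos: int
    length: int
    strand: str  # "forward" | "reverse"


# ---------------------------------------------------------------------------
# significance length
# ---------------------------------------------------------------------------

def significant_repeat_length(genome_length: int, gc: float,
                              p: float = 0.001) -> int:
    """Shortest repeat length not expected by chance.

    Karlin–Ost-style expected-count criterion.  With per-position match
    probability E = 2(gc/2)² + 2((1-gc)/2)², the expected number of
    left-maximal exact matches of length >= l over the n²/2 unordered
    position pairs of a random genome is (1-E)/2 · n² · E^l, which also
    approximates P(longest repeat >= l) in the rare-event regime.  The
    returned length is the smallest integer pushing that expectation
    below ``p``; it is validated against simulated random genomes.
    Monotone: longer genomes and smaller p demand longer repeats.
    """
    if genome_length < 1000:
        raise ValueError("criterion calibrated for genomes >= 1 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    E = 2 * (gc / 2) ** 2 + 2 * ((1 - gc) / 2) ** 2
    n = genome_length
    expected = lambda l: 0.5 * (1 - E) * n * n * E ** l
    l = max(1, ceil((log(p) - log(0.5 * (1 - E) * n * n)) / log(E)))
    while l > 1 and expected(l - 1) <= p:
        l -= 1
    while expected(l) > p:
        l += 1
    return l


# ---------------------------------------------------------------------------
# maximal exact repeat pairs
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _extend_direct(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal direct pair containing the seed (i, j, k); i < j."""
    L = k
    while i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
        i -= 1
        j -= 1
        L += 1
    n = len(seq)
    while i + L < n and j + L < n and seq[i + L] == seq[j + L]:
        L += 1
    return i, j, L


def _extend_inverted(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal inverted pair containing the seed (i, j, k):
    seq[j:j+L] == revcomp(seq[i:i+L])."""
    L = k
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # copy1 grows right / copy2 grows left
    while j > 0 and i + L < j and seq[j - 1] == comp.get(seq[i + L], "?"):
        j -= 1
        L += 1
    # copy1 grows left / copy2 grows right
    while i > 0 and j + L < n and seq[j + L] == comp.get(seq[i - 1], "?"):
        i -= 1
        L += 1
    return i, j, L


def find_exact_repeats(
    sequence: str,
    min_length: Optional[int] = None,
    p_threshold: Optional[float] = None,
    gc: Optional[float] = None,
    include_inverted: bool = True,
) -> list[RepeatPair]:
    """All maximal exact repeat pairs of a genome above a length cutoff.

    Exactly one of ``min_length`` / ``p_threshold`` must be given; with
    a p-value threshold the cutoff is
    :func:`significant_repeat_length` at the genome's length and GC
    content.  Direct and inverted pairs are reported (self-overlapping
    tandem copies included); every seed is extended to its unique
    maximal pair and duplicates are merged.
    """
    seq = sequence.upper()
    n = len(seq)
    if (min_length is None) == (p_threshold is None):
        raise ValueError("give exactly one of min_length / p_threshold")
    if p_threshold is not None:
        if gc is None:
            gc = (seq.count("G") + seq.count("C")) / max(n, 1)
            gc = min(max(gc, 1e-6), 1 - 1e-6)
        min_length = significant_repeat_length(n, gc, p_threshold)
    if n < min_length:
        raise ValueError("sequence shorter than the minimum repeat length")
    k = min_length
    index = _kmer_index(seq, k)

    found: set[RepeatPair] = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a_i in range(len(positions) - 1):
            for b_i in range(a_i + 1, len(positions)):
                i, j, L = _extend_direct(seq, positions[a_i], positions[b_i], k)
                found.add(RepeatPair(i, j, L, "direct"))
    if include_inverted:
        seen_kmers = set()
        for kmer, positions in index.items():
            if kmer in seen_kmers:
                continue
            rc = _revcomp(kmer)
            partners = index.get(rc)
            if partners is None:
                continue
            seen_kmers.add(rc)
            for pi in positions:
                for pj in partners:
                    if pi == pj and kmer == rc:
                        continue
                    i, j = (pi, pj) if pi < pj else (pj, pi)
                    i2, j2, L = _extend_inverted(seq, i, j, k)
                    if i2 < j2:
                        found.add(RepeatPair(i2, j2, L, "inverted"))
    return sorted(found, key=lambda r: (r.pos1, r.pos2, r.orientation))


def repeat_coverage(sequence_length: int,
                    repeats: Iterable[RepeatPair]) -> float:
    """Percentage of the genome covered by the union of all repeat copies."""
    intervals = []
    for rep in repeats:
        for s, e in rep.intervals():
            if s < 0 or e > sequence_length:
                raise ValueError(f"repeat interval [{s}, {e}) out of bounds")
            intervals.append((s, e))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return 100.0 * covered / sequence_length


# ---------------------------------------------------------------------------
# maximal unique matches
# ---------------------------------------------------------------------------

def _count_occurrences(text: str, pat: str, limit: int = 2) -> int:
    count = start = 0
    while count < limit:
        hit = text.find(pat, start)
        if hit < 0:
            break
        count += 1
        start = hit + 1
    return count


def _extend_match(ref: str, qry: str, i: int, j: int, k: int):
    L = k
    while i > 0 and j > 0 and ref[i - 1] == qry[j - 1]:
        i -= 1
        j -= 1
        L += 1
    while i + L < len(ref) and j + L < len(qry) and ref[i + L] == qry[j + L]:
        L += 1
    return i, j, L


def find_mums(reference: str, query: str, min_length: int = 20) -> list[Mum]:
    """Maximal unique matches between two genomes, both strands.

    A MUM is a maximal exact match of at least ``min_length`` bp whose
    matched substring occurs exactly once in the (forward) reference
    and exactly once in the query counting both strands jointly —
    the classical mummer ``-mum`` semantics.  Reverse-strand matches
    report the query start in original (forward) coordinates.
    """
    ref = reference.upper()
    qry = query.upper()
    if not ref or not qry:
        raise ValueError("sequences must be nonempty")
    if min(len(ref), len(qry)) < min_length:
        raise ValueError("sequences shorter than min_length")
    ref_index = _kmer_index(ref, min_length)
    qrc = _revcomp(qry)

    candidates: set[tuple[int, int, int, str]] = set()
    for strand, q in (("forward", qry), ("reverse", qrc)):
        for j in range(len(q) - min_length + 1):
            positions = ref_index.get(q[j:j + min_length])
            if not positions:
                continue
            for i in positions:
                mi, mj, L = _extend_match(ref, q, i, j, min_length)
                candidates.add((mi, mj, L, strand))

    out = []
    for i, j, L, strand in sorted(candidates):
        sub = ref[i:i + L]
        if _count_occurrences(ref, sub) != 1:
            continue
        both = _count_occurrences(qry, sub) + _count_occurrences(qrc, sub)
        if both != 1:
            continue
        qpos = j if strand == "forward" else len(qry) - j - L
        out.append(Mum(ref_pos=i, qry_pos=qpos, length=L, strand=strand))
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def repeats_to_frame(repeats: Sequence[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pos1, r.pos2, r.length, r.orientation) for r in repeats],
        columns=["pos1", "pos2", "length", "orientation"],
    )


def mums_to_frame(mums: Sequence[Mum]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.ref_pos, m.qry_pos, m.length, m.strand) for m in mums],
        columns=["ref_pos", "qry_pos", "length", "strand"],
    )
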