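"""Ortholog mapping from reciprocal protein hit tables.

Orthologs between two genomes are operationalized as best bidirectional
hits: gene ``b`` is ``a``'s highest-scoring hit and vice versa, after
discarding hits below 40% identity or with protein lengths differing by
more than 20%.  The resulting one-to-one map, combined with gene ranks
and strands from the two annotations, is the input for every
rearrangement measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .permutation import SignedPermutation

__all__ = [
    "HitRecord",
    "OrthologMap",
    "read_hit_table",
    "write_hit_table",
    "filter_hits",
    "best_bidirectional_hits",
    "map_to_permutation",
    "subsample_map",
]

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein hit (a row of the 12-column tabular format)."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_length: int
    subject_length: int
    score: float

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity must be in [0, 100]")
        if self.query_length <= 0 or self.subject_length <= 0:
            raise ValueError("lengths must be positive")
        if self.score < 0:
            raise ValueError("score must be nonnegative")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hit file.

    Protein lengths are taken from ``qend`` / ``send``: the simulator
    (and any full-length alignment) writes coordinates spanning the whole
    protein, so the end coordinate equals its length.
    """
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, dtype={"query": str, "subject": str})
    return [
        HitRecord(r.query, r.subject, float(r.pident), int(r.qend), int(r.send),
                  float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    rows = [
        (h.query_id, h.subject_id, round(h.percent_identity, 2),
         max(h.query_length, h.subject_length), 0, 0,
         1, h.query_length, 1, h.subject_length, 1e-30, round(h.score, 1))
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False,
                                                   header=False)


def filter_hits(hits: Sequence[HitRecord], min_identity: float = 40.0,
                max_length_diff: float = 0.2) -> list[HitRecord]:
    """Keep hits with identity >= ``min_identity`` and length difference
    ``|lq - ls| / max(lq, ls)`` <= ``max_length_diff`` (both inclusive)."""
    if not (0 <= min_identity <= 100) or not (0 <= max_length_diff <= 1):
        raise ValueError("thresholds out of range")
    out = []
    for h in hits:
        if h.percent_identity < min_identity:
            continue
        ldiff = abs(h.query_length - h.subject_length) / max(h.query_length,
                                                            h.subject_length)
        if ldiff <= max_length_diff:
            out.append(h)
    return out


@dataclass
class OrthologMap:
    """One-to-one gene pairing between two genomes.

    Arrays are aligned by pair index: ``rank_a[i]`` is the position
    (0..n-1 along replicon A) of ``genes_a[i]``, etc.  Strands are
    "+"/"-".  Ranks within each genome must be distinct.
    """

    genes_a: np.ndarray
    genes_b: np.ndarray
    rank_a: np.ndarray
    rank_b: np.ndarray
    strand_a: np.ndarray
    strand_b: np.ndarray
    circular_a: bool = True
    circular_b: bool = True

    def __post_init__(self):
        n = len(self.genes_a)
        for name in ("genes_b", "rank_a", "rank_b", "strand_a", "strand_b"):
            if len(getattr(self, name)) != n:
                raise ValueError("all pair arrays must have equal length")
        for ranks in (self.rank_a, self.rank_b):
            if len(np.unique(ranks)) != n:
                raise ValueError("ranks within a genome must be distinct")
        if len(np.unique(self.genes_a)) != n or len(np.unique(self.genes_b)) != n:
            raise ValueError("mapping must be one-to-one")

    def __len__(self) -> int:
        return len(self.genes_a)

    @property
    def circular(self) -> bool:
        return self.circular_a and self.circular_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_a": self.genes_a, "gene_b": self.genes_b,
            "rank_a": self.rank_a, "rank_b": self.rank_b,
            "strand_a": self.strand_a, "strand_b": self.strand_b,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, circular_a: bool = True,
                   circular_b: bool = True) -> "OrthologMap":
        return cls(
            genes_a=df["gene_a"].to_numpy(), genes_b=df["gene_b"].to_numpy(),
            rank_a=df["rank_a"].to_numpy(int), rank_b=df["rank_b"].to_numpy(int),
            strand_a=df["strand_a"].to_numpy(), strand_b=df["strand_b"].to_numpy(),
            circular_a=circular_a, circular_b=circular_b,
        )

    # convenience used throughout: the pair set is symmetric in A/B
    def swapped(self) -> "OrthologMap":
        return OrthologMap(
            genes_a=self.genes_b, genes_b=self.genes_a,
            rank_a=self.rank_b, rank_b=self.rank_a,
            strand_a=self.strand_b, strand_b=self.strand_a,
            circular_a=self.circular_b, circular_b=self.circular_a,
        )


def _best_per_query(hits: Sequence[HitRecord]) -> dict[str, str]:
    """Best subject per query: highest score, ties broken by higher
    identity, then lexicographically smaller subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.score, h.percent_identity)
        cur_key = (cur.score, cur.percent_identity)
        if key > cur_key or (key == cur_key and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def best_bidirectional_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    annot_a: Optional[GenomeAnnotation] = None,
    annot_b: Optional[GenomeAnnotation] = None,
) -> OrthologMap:
    """Reciprocal-best pairing of two (already filtered) hit lists.

    When annotations are supplied, ranks and strands are attached from
    them (pairs whose genes are absent from the annotations are dropped);
    otherwise genes are ranked by their order of first appearance in the
    hit tables, which is the replicon order for files written by this
    package.
    """
    ab = _best_per_query(hits_ab)
    ba = _best_per_query(hits_ba)
    pairs = sorted((a, b) for a, b in ab.items() if ba.get(b) == a)

    if annot_a is not None and annot_b is not None:
        ra = annot_a.gene_ranks()
        rb = annot_b.gene_ranks()
        pairs = [(a, b) for a, b in pairs if a in ra.index and b in rb.index]
        rank_a = np.array([ra.loc[a, "rank"] for a, _ in pairs], dtype=int)
        rank_b = np.array([rb.loc[b, "rank"] for _, b in pairs], dtype=int)
        strand_a = np.array([ra.loc[a, "strand"] for a, _ in pairs])
        strand_b = np.array([rb.loc[b, "strand"] for _, b in pairs])
        circ_a, circ_b = annot_a.circular, annot_b.circular
    else:
        order_a = {h.query_id: i for i, h in enumerate(hits_ab)}
        order_b = {h.query_id: i for i, h in enumerate(hits_ba)}
        ra_sorted = {g: i for i, g in enumerate(sorted({a for a, _ in pairs},
                                                       key=lambda g: order_a.get(g, 0)))}
        rb_sorted = {g: i for i, g in enumerate(sorted({b for _, b in pairs},
                                                       key=lambda g: order_b.get(g, 0)))}
        rank_a = np.array([ra_sorted[a] for a, _ in pairs], dtype=int)
        rank_b = np.array([rb_sorted[b] for _, b in pairs], dtype=int)
        strand_a = np.full(len(pairs), "+")
        strand_b = np.full(len(pairs), "+")
        circ_a = circ_b = True

    return OrthologMap(
        genes_a=np.array([a for a, _ in pairs], dtype=object),
        genes_b=np.array([b for _, b in pairs], dtype=object),
        rank_a=rank_a, rank_b=rank_b,
        strand_a=strand_a, strand_b=strand_b,
        circular_a=circ_a, circular_b=circ_b,
    )


def map_to_permutation(omap: OrthologMap) -> SignedPermutation:
    """Signed permutation of genome B's gene order in genome-A labels.

    Genes are numbered 1..n by rank in genome A (A's strand taken as +);
    the permutation lists those labels in genome B's rank order, negated
    where the two copies disagree in strand.
    """
    if len(omap) == 0:
        raise ValueError("empty ortholog map")
    n = len(omap)
    label = np.empty(n, dtype=np.int64)
    label[np.argsort(omap.rank_a, kind="stable")] = np.arange(1, n + 1)
    sign = np.where(omap.strand_a == omap.strand_b, 1, -1)
    order_b = np.argsort(omap.rank_b, kind="stable")
    return SignedPermutation((sign * label)[order_b], circular=omap.circular)


def subsample_map(omap: OrthologMap, n: int,
                  rng: np.random.Generator) -> OrthologMap:
    """Uniform subsample of ``min(n, len(map))`` pairs without
    replacement, with ranks relabelled 0..m-1 preserving relative order."""
    if len(omap) < 2:
        raise ValueError("map must contain at least 2 pairs")
    if n < 2:
        raise ValueError("subsample size must be at least 2")
    m = min(n, len(omap))
    idx = np.sort(rng.choice(len(omap), size=m, replace=False))
    ra = omap.rank_a[idx]
    rb = omap.rank_b[idx]
    new_ra = np.empty(m, dtype=np.int64)
    new_ra[np.argsort(ra, kind="stable")] = np.arange(m)
    new_rb = np.empty(m, dtype=np.int64)
    new_rb[np.argsort(rb, kind="stable")] = np.arange(m)
    return OrthologMap(
        genes_a=omap.genes_a[idx], genes_b=omap.genes_b[idx],
        rank_a=new_ra, rank_b=new_rb,
        strand_a=omap.strand_a[idx], strand_b=omap.strand_b[idx],
        circular_a=omap.circular_a, circular_b=omap.circular_b,
    )
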