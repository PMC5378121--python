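"""Nucleotide genomes and aligned 16S pairs.

Genomes are random sequences with controllable GC content, a GC-skew
sign switch at the replication origin and its antipode, planted exact
repeats, and rRNA gene annotations — fixtures for the genome-feature
and repeat-scanning stages.  16S pairs are evolved under the HKY
substitution model at a known divergence.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from ..annotation import GenomeAnnotation
from ..divergence import BASES, hky_rate_matrix

__all__ = ["simulate_nucleotide_genome", "simulate_aligned_16s"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def simulate_nucleotide_genome(
    length: int,
    gc: float = 0.5,
    skew_amp: float = 0.0,
    oric: int = 0,
    planted_repeats: Sequence[tuple[int, str, int]] = (),
    rrna_positions: Sequence[int] = (),
    rng: np.random.Generator | int | None = None,
    rrna_length: int = 1500,
) -> tuple[str, GenomeAnnotation]:
    """Random circular genome with a planted replication-origin signature.

    The replichore from ``oric`` to its antipode is G-enriched on the
    published strand (P(G), P(C) = gc/2·(1±skew_amp)) and the other arc
    mirrored, so the recovered ΔGC skew is ≈ 2·skew_amp.  Each entry of
    ``planted_repeats`` is (repeat_length, "direct"|"inverted", copies):
    a source segment plus copies placed without overlap.  rRNA genes of
    ``rrna_length`` bp are annotated at the requested start positions.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for rep_len, _orient, _copies in planted_repeats:
        if rep_len >= length // 2:
            raise ValueError("planted repeat length must be < length/2")

    at = (1.0 - gc) / 2.0
    pos = np.arange(length)
    ter = (oric + length // 2) % length
    if oric <= ter:
        arc1 = (pos >= oric) & (pos < ter)
    else:
        arc1 = (pos >= oric) | (pos < ter)
    pg = np.where(arc1, gc / 2 * (1 + skew_amp), gc / 2 * (1 - skew_amp))
    pc = gc - pg
    u = rng.random(length)
    seq = np.full(length, "A", dtype="<U1")
    seq[u < pg] = "G"
    seq[(u >= pg) & (u < pg + pc)] = "C"
    seq[(u >= pg + pc) & (u < pg + pc + at)] = "A"
    seq[u >= pg + pc + at] = "T"

    # plant exact repeats over the background, without overlaps
    taken: list[tuple[int, int]] = []

    def _reserve(start: int, ln: int) -> bool:
        for s, e in taken:
            if start < e and s < start + ln:
                return False
        taken.append((start, start + ln))
        return True

    for rep_len, orient, copies in planted_repeats:
        placed = False
        for _ in range(1000):
            src = int(rng.integers(0, length - rep_len))
            if _reserve(src, rep_len):
                placed = True
                break
        if not placed:
            raise ValueError("could not place planted repeat source")
        unit = "".join(seq[src:src + rep_len])
        for _ in range(copies):
            ok = False
            for _ in range(1000):
                dst = int(rng.integers(0, length - rep_len))
                if _reserve(dst, rep_len):
                    ok = True
                    break
            if not ok:
                raise ValueError("could not place planted repeat copy "
                                 "(overlapping repeats cannot be placed)")
            text = unit if orient == "direct" else _revcomp(unit)
            seq[dst:dst + rep_len] = list(text)

    genes = []
    for i, start in enumerate(rrna_positions):
        end = min(start + rrna_length, length)
        genes.append({"gene_id": f"rrn{i + 1}", "start": int(start),
                      "end": int(end), "strand": "+", "is_rrna": True})
    import pandas as pd
    annot = GenomeAnnotation(
        replicon_id="simulated", length=length, circular=True, oric=oric,
        genes=pd.DataFrame(genes, columns=["gene_id", "start", "end", "strand",
                                           "is_rrna"]),
    )
    return "".join(seq), annot


def simulate_aligned_16s(
    x: float,
    kappa: float = 2.0,
    freqs: Optional[Sequence[float]] = None,
    length: int = 1500,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """An aligned sequence pair at total divergence ``x`` under HKY.

    One sequence is drawn from the stationary base frequencies and the
    other evolved from it for time ``x`` (HKY is reversible, so this
    equals placing them ``x`` apart on a two-branch tree).  The rate
    matrix is scaled so ``x`` is in expected substitutions per site.
    """
    if x < 0:
        raise ValueError("divergence must be nonnegative")
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0) or (freqs <= 0).any():
        raise ValueError("freqs must be 4 positive values summing to 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    anc_idx = rng.choice(4, size=length, p=freqs)
    seq_a = "".join(BASES[i] for i in anc_idx)
    if x == 0:
        return seq_a, seq_a
    P = expm(hky_rate_matrix(kappa, freqs) * x)
    der_idx = np.empty(length, dtype=np.int64)
    for i in range(4):
        mask = anc_idx == i
        if mask.any():
            der_idx[mask] = rng.choice(4, size=int(mask.sum()), p=P[i])
    seq_b = "".join(BASES[i] for i in der_idx)
    return seq_a, seq_b
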