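"""Genomic indicators of selection on genome organization.

Five replication-related features quantify how "structured" a genome
is: the fraction of genes on the leading strands, rRNA gene count,
mean rRNA–origin distance, ΔGC skew between leading and lagging
strands, and the ratio of single genes (operon-free genes).  Relaxed
selection on genome organization would show as lower leading-strand
fraction, fewer rRNA genes, larger rRNA–origin distance, lower ΔGC
skew and a larger single-gene ratio; group contrasts are one-tailed
Welch t-tests in those directions with Bonferroni control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .annotation import GenomeAnnotation

__all__ = [
    "SelectionIndicators",
    "leading_strand_fraction",
    "delta_gc_skew",
    "rrna_statistics",
    "single_gene_ratio",
    "selection_indicators",
    "compare_indicator_groups",
]

# direction in which each indicator moves under *relaxed* selection
RELAXED_DIRECTION = {
    "leading_strand_fraction": "less",
    "rrna_count": "less",
    "delta_gc_skew": "less",
    "rrna_ori_distance_mean": "greater",
    "single_gene_ratio": "greater",
}


@dataclass(frozen=True)
class SelectionIndicators:
    leading_strand_fraction: float
    rrna_count: int
    rrna_ori_distance_mean: float     # bp; nan when no rRNA genes
    delta_gc_skew: float
    single_gene_ratio: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in RELAXED_DIRECTION}


def _gene_midpoints(annot: GenomeAnnotation) -> np.ndarray:
    g = annot.genes
    return ((g["start"].to_numpy() + g["end"].to_numpy()) / 2) % annot.length


def _arc_mask(positions: np.ndarray, start: int, end: int, length: int) -> np.ndarray:
    """Membership of circular positions in the arc [start, end)."""
    start %= length
    end %= length
    if start <= end:
        return (positions >= start) & (positions < end)
    return (positions >= start) | (positions < end)


def leading_strand_fraction(annot: GenomeAnnotation) -> float:
    """Fraction of genes on the leading strands of the two replichores.

    The circle splits at oriC and the antipodal terminus; within each
    replichore the leading strand is the strand carrying more genes
    (genes are assigned by midpoint).  Ties contribute half their
    replichore's genes, so the result is >= 0.5 by construction.
    """
    if annot.oric is None:
        raise ValueError("oriC unknown: leading-strand fraction undefined")
    if len(annot) == 0:
        raise ValueError("no genes")
    mids = _gene_midpoints(annot)
    strands = annot.genes["strand"].to_numpy()
    ter = (annot.oric + annot.length // 2) % annot.length
    on_leading = 0.0
    for a, b in ((annot.oric, ter), (ter, annot.oric)):
        in_arc = _arc_mask(mids, a, b, annot.length)
        plus = int(((strands == "+") & in_arc).sum())
        minus = int(in_arc.sum()) - plus
        on_leading += max(plus, minus) if plus != minus else in_arc.sum() / 2
    return on_leading / len(annot)


def delta_gc_skew(sequence: str, oric: int,
                  concatenate_leading: bool = False) -> float:
    """ΔGC skew: (G−C)/(G+C) difference between leading and lagging arcs.

    The published strand is split at oriC and the antipodal terminus
    into two arcs; each arc's skew is (G−C)/(G+C) and the arc with more
    G's is labelled leading.  ``concatenate_leading`` instead computes
    skews on the leading-strand sequence of each replichore
    (reverse-complementing the lagging-arc) — same magnitude, different
    sign convention for the second arc.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        raise ValueError("sequence too short")
    if not 0 <= oric < n:
        raise ValueError("oriC outside sequence")
    ter = (oric + n // 2) % n
    if oric < ter:
        arcs = [seq[oric:ter], seq[ter:] + seq[:oric]]
    else:
        arcs = [seq[oric:] + seq[:ter], seq[ter:oric]]
    if concatenate_leading:
        comp = str.maketrans("ACGT", "TGCA")
        arcs = [arcs[0], arcs[1].translate(comp)[::-1]]
    skews, g_counts = [], []
    for arc in arcs:
        g, c = arc.count("G"), arc.count("C")
        if g + c == 0:
            raise ValueError("an arc contains no G or C")
        skews.append((g - c) / (g + c))
        g_counts.append(g)
    lead = int(g_counts[1] > g_counts[0])
    return skews[lead] - skews[1 - lead]


def rrna_statistics(annot: GenomeAnnotation) -> tuple[int, float]:
    """(number of rRNA genes, mean circular rRNA-midpoint–oriC distance).

    The mean distance is nan when the count is 0; requesting it without
    a known oriC raises.
    """
    rr = annot.genes[annot.genes["is_rrna"]]
    count = len(rr)
    if count == 0:
        return 0, float("nan")
    if annot.oric is None:
        raise ValueError("oriC unknown: rRNA-origin distance undefined")
    mids = ((rr["start"].to_numpy() + rr["end"].to_numpy()) / 2) % annot.length
    raw = np.abs(mids - annot.oric)
    circ = np.minimum(raw, annot.length - raw)
    return count, float(circ.mean())


def single_gene_ratio(annot: GenomeAnnotation) -> float:
    """Ratio of genes whose two circular neighbours are both on the
    opposite strand (genes outside any same-orientation run / operon)."""
    if len(annot) < 3:
        raise ValueError("need at least 3 genes")
    s = annot.genes["strand"].to_numpy()
    prev_s = np.roll(s, 1)
    next_s = np.roll(s, -1)
    single = (s != prev_s) & (s != next_s)
    return float(single.mean())


def selection_indicators(annot: GenomeAnnotation,
                         sequence: Optional[str] = None) -> SelectionIndicators:
    """All five indicators for one genome (skew needs the sequence)."""
    count, dist = rrna_statistics(annot) if annot.oric is not None else (
        annot.n_rrna, float("nan"))
    return SelectionIndicators(
        leading_strand_fraction=leading_strand_fraction(annot)
        if annot.oric is not None and len(annot) else float("nan"),
        rrna_count=count,
        rrna_ori_distance_mean=dist,
        delta_gc_skew=delta_gc_skew(sequence, annot.oric)
        if sequence is not None and annot.oric is not None else float("nan"),
        single_gene_ratio=single_gene_ratio(annot) if len(annot) >= 3
        else float("nan"),
    )


def compare_indicator_groups(
    indicators_r: Sequence[SelectionIndicators],
    indicators_n: Sequence[SelectionIndicators],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Welch t-tests for relaxed selection in the R group.

    Each indicator is tested in its relaxation direction (see
    ``RELAXED_DIRECTION``); the Bonferroni flag corrects over the five
    indicators.  Genomes with a nan value for an indicator are dropped
    from that comparison.
    """
    if len(indicators_r) < 2 or len(indicators_n) < 2:
        raise ValueError("each group needs at least 2 genomes")
    rows = []
    for name, direction in RELAXED_DIRECTION.items():
        r = np.array([getattr(i, name) for i in indicators_r], float)
        n = np.array([getattr(i, name) for i in indicators_n], float)
        r, n = r[~np.isnan(r)], n[~np.isnan(n)]
        if r.size < 2 or n.size < 2:
            rows.append({"indicator": name, "t": np.nan, "p": np.nan,
                         "significant": False, "bonferroni_significant": False})
            continue
        if np.var(r) == 0 and np.var(n) == 0:
            # constant groups: no evidence either way when equal, full
            # separation otherwise (in the tested direction)
            if r[0] == n[0]:
                t_val, p_val = 0.0, 0.5
            else:
                relaxed = (r[0] < n[0]) == (direction == "less")
                t_val = np.inf * (-1 if direction == "less" else 1) * \
                    (1 if relaxed else -1)
                p_val = 0.0 if relaxed else 1.0
            rows.append({"indicator": name, "t": float(t_val), "p": p_val,
                         "significant": p_val < alpha,
                         "bonferroni_significant":
                             p_val < alpha / len(RELAXED_DIRECTION)})
            continue
        stat = ttest_ind(r, n, equal_var=False, alternative=direction)
        rows.append({
            "indicator": name,
            "t": float(stat.statistic),
            "p": float(stat.pvalue),
            "significant": bool(stat.pvalue < alpha),
            "bonferroni_significant": bool(stat.pvalue < alpha / len(RELAXED_DIRECTION)),
        })
    return pd.DataFrame(rows)
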