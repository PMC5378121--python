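"""Pairwise 16S divergence under the HKY substitution model.

The evolutionary-time axis of the decay model is the pairwise maximum
likelihood distance between aligned 16S rRNA sequences under HKY
(transition/transversion ratio κ, arbitrary base frequencies).  Gappy
alignment columns are dropped by a one-parameter filter first.  With
κ = 1 and equal frequencies the estimate reduces to the Jukes–Cantor
closed form, which anchors the numerical tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "BASES",
    "hky_rate_matrix",
    "filter_alignment_columns",
    "hky_ml_distance",
    "DivergenceMatrix",
    "pairwise_divergence_matrix",
    "read_fasta_alignment",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SATURATION_CAP = 5.0  # substitutions/site; distances beyond are reported capped


def hky_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY85 rate matrix (A, C, G, T order), scaled to one expected
    substitution per site per unit time at stationarity."""
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("freqs must be 4 values summing to 1")
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _as_matrix(alignment) -> tuple[list[str], np.ndarray]:
    """Normalize an alignment (MultipleSeqAlignment, SeqRecords, or
    (id, seq) pairs) into ids + an upper-case character matrix."""
    ids, seqs = [], []
    for rec in alignment:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            ids.append(str(rec.id))
            seqs.append(str(rec.seq).upper())
        else:
            name, seq = rec
            ids.append(str(name))
            seqs.append(str(seq).upper())
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    mat = np.array([list(s) for s in seqs], dtype="<U1")
    return ids, mat


def filter_alignment_columns(alignment, max_gap_fraction: float = 0.5):
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    A lightweight surrogate for block-based alignment trimming: rows
    keep their order, and ('id', sequence) pairs are returned.
    """
    ids, mat = _as_matrix(alignment)
    gaps = np.isin(mat, ("-", ".", "~"))
    keep = gaps.mean(axis=0) <= max_gap_fraction
    filtered = mat[:, keep]
    return [(i, "".join(row)) for i, row in zip(ids, filtered)]


def read_fasta_alignment(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# pairwise ML distance
# ---------------------------------------------------------------------------

def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    a = np.array(list(seq_a.upper()), dtype="<U1")
    b = np.array(list(seq_b.upper()), dtype="<U1")
    if a.size != b.size:
        raise ValueError("sequences must have equal aligned length")
    ia = np.array([_BASE_INDEX.get(c, -1) for c in a])
    ib = np.array([_BASE_INDEX.get(c, -1) for c in b])
    ok = (ia >= 0) & (ib >= 0)
    if not ok.any():
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    counts = np.zeros((4, 4))
    np.add.at(counts, (ia[ok], ib[ok]), 1.0)
    return counts


def _nll(counts: np.ndarray, t: float, kappa: float, pi: np.ndarray) -> float:
    P = expm(hky_rate_matrix(kappa, pi) * t)
    with np.errstate(divide="ignore"):
        logterm = np.log(np.maximum(pi[:, None] * P, 1e-300))
    return -float(np.sum(counts * logterm))


def hky_ml_distance(
    seq_a: str,
    seq_b: str,
    kappa: float | str = "estimate",
    freqs: Optional[Sequence[float]] = None,
) -> float:
    """Maximum likelihood HKY distance between two aligned sequences.

    Maximizes the pairwise likelihood over the branch length t (and κ
    when ``kappa='estimate'``); base frequencies default to the
    empirical frequencies of the pair.  Returns expected substitutions
    per site; saturated pairs are capped at 5 with a warning.
    """
    counts = _pair_counts(seq_a, seq_b)
    if freqs is None:
        marg = counts.sum(axis=1) + counts.sum(axis=0)
        pi = marg / marg.sum()
        pi = np.maximum(pi, 1e-6)
        pi = pi / pi.sum()
    else:
        pi = np.asarray(freqs, dtype=float)
    if counts.sum() == np.trace(counts):
        return 0.0

    if isinstance(kappa, str):
        if kappa != "estimate":
            raise ValueError("kappa must be a number or 'estimate'")
        res = minimize(
            lambda v: _nll(counts, np.exp(v[0]), np.exp(v[1]), pi),
            x0=np.array([np.log(0.1), np.log(2.0)]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        t = float(np.exp(res.x[0]))
    else:
        res = minimize_scalar(
            lambda v: _nll(counts, np.exp(v), float(kappa), pi),
            bounds=(np.log(1e-9), np.log(SATURATION_CAP * 2)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        t = float(np.exp(res.x))
    if not np.isfinite(t):
        raise RuntimeError("non-finite likelihood optimum")
    if t >= SATURATION_CAP:
        warnings.warn(
            f"pairwise distance saturated; capping at {SATURATION_CAP} "
            "substitutions/site", RuntimeWarning)
        t = SATURATION_CAP
    return t


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DivergenceMatrix:
    """Symmetric matrix of pairwise distances (substitutions/site)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.to_frame().loc[a, b])

    # PHYLIP square format ------------------------------------------------
    def write_phylip(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.values):
                cells = " ".join(f"{v:.9f}" for v in row)
                fh.write(f"{name:<12s}{cells}\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DivergenceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        ids, rows = [], []
        for ln in lines[1:1 + n]:
            parts = ln.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:1 + n]])
        return cls(ids=ids, values=np.array(rows))


def pairwise_divergence_matrix(
    alignment,
    max_gap_fraction: float = 0.5,
    kappa: float | str = "estimate",
    freqs: Optional[Sequence[float]] = None,
) -> DivergenceMatrix:
    """Column-filter an alignment and compute all pairwise HKY distances."""
    records = filter_alignment_columns(alignment, max_gap_fraction)
    ids = [r[0] for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = hky_ml_distance(records[i][1], records[j][1], kappa=kappa,
                                freqs=freqs)
            mat[i, j] = mat[j, i] = d
    return DivergenceMatrix(ids=ids, values=mat)
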