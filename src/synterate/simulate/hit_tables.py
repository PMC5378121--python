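"""Reciprocal protein hit tables for a simulated genome pair.

Every true ortholog pair (shared ancestral gene id) yields reciprocal
hits whose identity decays exponentially with the pair's divergence,
with matched protein lengths; spurious paralogous hits of lower score
can be mixed in to exercise the reciprocal-best filter.
"""

from __future__ import annotations

import numpy as np

from ..orthology import HitRecord
from .gene_orders import SyntheticClade

__all__ = ["simulate_hit_tables"]


def _gene_length(gene_id: int, base: int = 300, spread: int = 200) -> int:
    """Deterministic per-ancestral-gene protein length (aa).

    Hash-derived so that true orthologs always report matched lengths
    regardless of which genome pair is being compared.
    """
    h = (gene_id * 2654435761) % 2 ** 32
    return base + (h % spread)


def simulate_hit_tables(
    clade: SyntheticClade,
    species_a: str,
    species_b: str,
    identity_decay: float = 2.0,
    paralog_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    identity_noise_sd: float = 1.5,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Hit tables (A→B, B→A) for one genome pair of a simulated clade.

    True ortholog identity is ``100·exp(−identity_decay·x)`` plus
    Gaussian noise; each spurious paralog hit (drawn per true pair with
    probability ``paralog_rate``) links a gene to a random non-ortholog
    at ~70% of the orthologous identity and lower score.
    """
    if species_a not in clade.orders or species_b not in clade.orders:
        raise KeyError(f"unknown species: {species_a!r} / {species_b!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = clade.x(species_a, species_b)
    shared = sorted(clade.retained[species_a] & clade.retained[species_b])
    base_identity = 100.0 * np.exp(-identity_decay * x)

    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    for g in shared:
        length = _gene_length(g)
        ident = float(np.clip(base_identity + rng.normal(0, identity_noise_sd),
                              1.0, 100.0))
        score = 2.0 * length * ident / 100.0
        qa, qb = f"g{g}", f"g{g}"
        hits_ab.append(HitRecord(qa, qb, ident, length, length, score))
        hits_ba.append(HitRecord(qb, qa, ident, length, length, score))
        if paralog_rate > 0 and rng.random() < paralog_rate:
            other = int(rng.choice(shared))
            if other != g:
                olen = _gene_length(other)
                pid = max(1.0, ident * 0.7)
                pscore = score * 0.6
                hits_ab.append(HitRecord(qa, f"g{other}", pid, length, olen, pscore))
                hits_ba.append(HitRecord(f"g{other}", qa, pid, olen, length, pscore))
    return hits_ab, hits_ba
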