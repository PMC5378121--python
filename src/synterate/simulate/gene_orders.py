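"""Clades of circular gene orders diverging by inversions.

Genomes are circular sequences of signed ancestral gene ids.  Along
each branch of a star or Yule tree, inversions arrive as a Poisson
process (radiation-resistant tips use a faster terminal-branch rate)
and genes are lost independently.  Two simulator knobs create the
structure the decay model expects: a *protected* fraction of ancestral
adjacencies that inversions may never cut (producing the saturation
floor of gene order conservation), and an optional bias toward
inversions symmetric about the replication origin.

The gene order of every tip is kept in "origin frame": the list starts
at the replication origin, so slot 0 of the circular order *is* oriC
and symmetric inversions mirror their endpoints about it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..orthology import OrthologMap
from ..permutation import SignedPermutation

__all__ = [
    "SimulationConfig",
    "SyntheticClade",
    "apply_random_inversion",
    "evolve_gene_orders",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic clade.

    Divergence is measured in expected 16S substitutions per site, so
    ``rate_N`` / ``rate_R`` are inversions per substitution/site.  The
    resistant-tip rate applies on terminal branches of R species only;
    internal branches always use ``rate_N``.
    """

    n_species: int = 12
    n_resistant: int = 0
    n_genes: int = 1000
    tree_model: str = "yule"          # {"star", "yule"}
    depth: float = 0.1                # root-to-tip height, substitutions/site
    rate_N: float = 1400.0            # inversions per unit divergence
    rate_R: float = 1400.0
    symmetric_prob: float = 0.0
    protected_frac: float = 0.0
    gene_loss_rate: float = 0.3       # per-gene loss intensity per unit divergence
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.n_genes < 1:
            raise ValueError("n_species and n_genes must be positive")
        if self.n_resistant > self.n_species or self.n_resistant < 0:
            raise ValueError("n_resistant must be in [0, n_species]")
        if self.tree_model not in ("star", "yule"):
            raise ValueError("tree_model must be 'star' or 'yule'")
        if self.depth <= 0:
            raise ValueError("tree depth must be positive")
        for r in (self.rate_N, self.rate_R, self.gene_loss_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        for p in (self.symmetric_prob,):
            if not 0 <= p <= 1:
                raise ValueError("symmetric_prob must be in [0, 1]")
        if not 0 <= self.protected_frac < 1:
            raise ValueError("protected_frac must be in [0, 1)")


def _protected_slots(order: list[int], protected: set[frozenset[int]]) -> np.ndarray:
    """Boolean mask over cut slots; slot s sits between positions s-1 and s."""
    n = len(order)
    mask = np.zeros(n, dtype=bool)
    for s in range(n):
        pair = frozenset((abs(order[s - 1]), abs(order[s])))
        mask[s] = pair in protected
    return mask


def _cut(order: list[int], a: int, b: int) -> list[int]:
    """Reverse (and sign-flip) the arc between slots a < b: positions a..b-1."""
    return order[:a] + [-g for g in reversed(order[a:b])] + order[b:]


def _draw_slots(n: int, allowed: np.ndarray, symmetric: bool, origin_slot: int,
                rng: np.random.Generator, max_tries: int = 200) -> tuple[int, int]:
    allowed_idx = np.flatnonzero(allowed)
    if allowed_idx.size < 2:
        raise RuntimeError("fewer than two cuttable adjacencies")
    for _ in range(max_tries):
        a = int(rng.choice(allowed_idx))
        if symmetric:
            # mirror about the origin slot, nudged to the nearest allowed slot
            b = (2 * origin_slot - a) % n
            for delta in (0, 1, -1, 2, -2):
                bb = (b + delta) % n
                if allowed[bb] and bb != a:
                    b = bb
                    break
            else:
                continue
        else:
            b = int(rng.choice(allowed_idx))
            if b == a:
                continue
        return (a, b) if a < b else (b, a)
    raise RuntimeError("could not draw a valid inversion (too many protected "
                       "adjacencies?)")


def apply_random_inversion(
    perm: SignedPermutation,
    rng: np.random.Generator,
    symmetric: bool = False,
    origin_index: Optional[int] = None,
    protected: Optional[set[frozenset[int]]] = None,
) -> SignedPermutation:
    """Apply one random inversion to a circular signed permutation.

    A contiguous segment is reversed and sign-flipped; its endpoints are
    chosen uniformly over cuttable adjacencies.  With ``symmetric=True``
    the two endpoints are mirror images about ``origin_index`` to the
    nearest gene.  Adjacencies listed in ``protected`` (unordered label
    pairs) are never cut.
    """
    if len(perm) < 2:
        raise ValueError("permutation too small to invert")
    if symmetric and origin_index is None:
        raise ValueError("symmetric inversion requires an origin index")
    order = list(perm.elements)
    n = len(order)
    allowed = ~_protected_slots(order, protected) if protected else np.ones(n, bool)
    a, b = _draw_slots(n, allowed, symmetric, origin_index or 0, rng)
    return SignedPermutation(_cut(order, a, b), circular=perm.circular)


@dataclass
class SyntheticClade:
    """A simulated clade: tip gene orders, labels, true divergences, events."""

    config: SimulationConfig
    species: list[str]
    resistance: dict[str, str]                   # species -> "R"/"N"
    divergence: pd.DataFrame                     # true pairwise x, symmetric
    orders: dict[str, list[int]]                 # signed ancestral gene ids, origin frame
    retained: dict[str, set[int]]
    events: list[dict]                           # per-branch event records
    protected: set[frozenset[int]] = field(default_factory=set)

    def ortholog_map(self, a: str, b: str) -> OrthologMap:
        """True one-to-one ortholog map between two tips, recovered from
        shared ancestral gene ids."""
        if a not in self.orders or b not in self.orders:
            raise KeyError(f"unknown species: {a!r} or {b!r}")
        shared = self.retained[a] & self.retained[b]
        oa = [g for g in self.orders[a] if abs(g) in shared]
        ob = [g for g in self.orders[b] if abs(g) in shared]
        rank_a = {abs(g): i for i, g in enumerate(oa)}
        strand_a = {abs(g): "+" if g > 0 else "-" for g in oa}
        genes = [abs(g) for g in ob]
        return OrthologMap(
            genes_a=np.array([f"g{g}" for g in genes], dtype=object),
            genes_b=np.array([f"g{g}" for g in genes], dtype=object),
            rank_a=np.array([rank_a[g] for g in genes], dtype=int),
            rank_b=np.arange(len(genes)),
            strand_a=np.array([strand_a[g] for g in genes]),
            strand_b=np.array(["+" if g > 0 else "-" for g in ob]),
        )

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for i, a in enumerate(self.species)
                for b in self.species[i + 1:]]

    def pair_category(self, a: str, b: str) -> str:
        labels = sorted((self.resistance[a], self.resistance[b]), reverse=True)
        return "".join(labels)  # "RR", "RN" or "NN"

    def x(self, a: str, b: str) -> float:
        return float(self.divergence.loc[a, b])

    def event_log_json(self) -> str:
        return json.dumps(self.events, indent=1)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _yule_tree(n: int, depth: float, rng: np.random.Generator):
    """Ultrametric pure-birth tree scaled to the requested height.

    Returns (parent, age, children, tips): node 0 is the root at age 0;
    tips all sit at age ``depth``.
    """
    parent = {0: None}
    age = {0: 0.0}
    children: dict[int, list[int]] = {0: []}
    active = [0]
    t = 0.0
    nxt = 1
    split_ages = []
    # draw split times of a standard Yule process, then rescale
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        split_ages.append(t)
        node = active.pop(int(rng.integers(k)))
        for _ in range(2):
            parent[nxt] = node
            children.setdefault(node, []).append(nxt)
            children[nxt] = []
            age[nxt] = t
            active.append(nxt)
            nxt += 1
    # total height: one more waiting time past the last split
    height = t + rng.exponential(1.0 / n)
    scale = depth / height
    age = {node: a * scale for node, a in age.items()}
    for tip in active:
        age[tip] = depth
    return parent, age, children, active


def _star_tree(n: int, depth: float):
    parent = {0: None}
    age = {0: 0.0}
    children = {0: list(range(1, n + 1))}
    for i in range(1, n + 1):
        parent[i] = 0
        age[i] = depth
        children[i] = []
    return parent, age, children, list(range(1, n + 1))


def evolve_gene_orders(config: SimulationConfig) -> SyntheticClade:
    """Simulate a clade of circular gene orders under the configured
    inversion / loss process.

    Per branch, the number of inversions is Poisson(rate × branch
    length) — ``rate_R`` on terminal branches of resistant species,
    ``rate_N`` elsewhere — and each gene survives the branch with
    probability exp(−gene_loss_rate × branch length).  The true pairwise
    divergence matrix and a per-branch event log are recorded.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    if config.tree_model == "star":
        parent, age, children, tips = _star_tree(n, config.depth)
    else:
        parent, age, children, tips = _yule_tree(n, config.depth, rng)

    # assign species names; resistant labels go to the first tips drawn
    tip_order = list(tips)
    rng.shuffle(tip_order)
    names = {}
    resistance = {}
    for i, node in enumerate(tip_order):
        nm = f"S{i + 1:02d}"
        names[node] = nm
        resistance[nm] = "R" if i < config.n_resistant else "N"

    root_order = list(range(1, config.n_genes + 1))
    n_protected = int(round(config.protected_frac * config.n_genes))
    protected_slots = rng.choice(config.n_genes, size=n_protected, replace=False)
    protected = {
        frozenset((root_order[s - 1], root_order[s])) for s in protected_slots
    }

    orders: dict[str, list[int]] = {}
    retained: dict[str, set[int]] = {}
    events: list[dict] = []

    def recurse(node: int, order: list[int]):
        for child in children[node]:
            blen = age[child] - age[node]
            is_tip = not children[child]
            label = resistance[names[child]] if is_tip else "N"
            rate = config.rate_R if (is_tip and label == "R") else config.rate_N
            child_order = list(order)
            # gene loss first, then inversions, along the branch
            lost = 0
            if config.gene_loss_rate > 0 and blen > 0:
                p_lose = 1.0 - np.exp(-config.gene_loss_rate * blen)
                keep = rng.random(len(child_order)) >= p_lose
                lost = int((~keep).sum())
                if len(child_order) - lost < 3:
                    keep[:] = True  # never wipe out a genome
                    lost = 0
                child_order = [g for g, k in zip(child_order, keep) if k]
            k_inv = int(rng.poisson(rate * blen)) if blen > 0 else 0
            applied = 0
            if k_inv and len(child_order) >= 3:
                allowed = ~_protected_slots(child_order, protected) \
                    if protected else np.ones(len(child_order), bool)
                for _ in range(k_inv):
                    try:
                        symmetric = bool(rng.random() < config.symmetric_prob)
                        a, b = _draw_slots(len(child_order), allowed, symmetric,
                                           0, rng)
                    except RuntimeError:
                        break
                    child_order = _cut(child_order, a, b)
                    if protected:
                        allowed = ~_protected_slots(child_order, protected)
                    applied += 1
            events.append({
                "parent": node, "child": child, "length": blen,
                "tip": names.get(child), "rate": rate,
                "inversions": applied, "genes_lost": lost,
            })
            if is_tip:
                nm = names[child]
                orders[nm] = child_order
                retained[nm] = {abs(g) for g in child_order}
            else:
                recurse(child, child_order)

    recurse(0, root_order)

    species = sorted(names.values())
    div = np.zeros((n, n))
    node_of = {v: k for k, v in names.items()}
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i < j:
                d = _tree_distance(node_of[a], node_of[b], parent, age)
                div[i, j] = div[j, i] = d
    divergence = pd.DataFrame(div, index=species, columns=species)
    return SyntheticClade(
        config=config, species=species, resistance=resistance,
        divergence=divergence, orders=orders, retained=retained,
        events=events, protected=protected,
    )


def _tree_distance(a: int, b: int, parent: dict, age: dict) -> float:
    anc_a = {}
    node = a
    while node is not None:
        anc_a[node] = age[a] - age[node]
        node = parent[node]
    node = b
    while node not in anc_a:
        node = parent[node]
    return anc_a[node] + (age[b] - age[node])
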