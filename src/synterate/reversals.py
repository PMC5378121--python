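"""Exact inversion (reversal) distances for signed permutations.

The minimum number of segment reversals transforming one signed gene
order into another is computed with Hannenhalli–Pevzner theory: frame
the permutation, build the breakpoint graph, and evaluate

    d = (n + 1) - c + h + f

where ``c`` counts alternating cycles, ``h`` hurdles (unoriented
components that do not separate other unoriented components) and ``f``
is 1 for the rare fortress configuration.  Circular permutations are
canonicalized by cutting the circle at gene 1 oriented + — reversal
distance on the circle equals the linear distance of the cut.

A breadth-first search over reversal moves (:func:`inversion_distance_bfs`)
is provided as a slow, assumption-free cross-check for small ``n``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .permutation import SignedPermutation

__all__ = [
    "inversion_distance",
    "inversion_distance_bfs",
    "breakpoint_graph_summary",
]


# ---------------------------------------------------------------------------
# breakpoint graph
# ---------------------------------------------------------------------------

def _frame(perm_elems: tuple[int, ...]) -> np.ndarray:
    """Double and frame a linear signed permutation.

    Element +x becomes the ordered pair (2x-1, 2x), -x becomes
    (2x, 2x-1); the sequence is framed by 0 and 2n+1.
    """
    n = len(perm_elems)
    s = np.empty(2 * n + 2, dtype=np.int64)
    s[0] = 0
    for i, e in enumerate(perm_elems):
        if e > 0:
            s[2 * i + 1] = 2 * e - 1
            s[2 * i + 2] = 2 * e
        else:
            s[2 * i + 1] = -2 * e
            s[2 * i + 2] = -2 * e - 1
    s[-1] = 2 * n + 1
    return s


@dataclass
class _Graph:
    """Breakpoint-graph bookkeeping for one linear permutation."""

    n: int
    cycles: int                 # all alternating cycles, trivial included
    hurdles: int
    fortress: bool

    @property
    def distance(self) -> int:
        return (self.n + 1) - self.cycles + self.hurdles + int(self.fortress)


def _analyze(perm_elems: tuple[int, ...]) -> _Graph:
    n = len(perm_elems)
    s = _frame(perm_elems)
    m = 2 * n + 2
    pos = np.empty(m, dtype=np.int64)
    pos[s] = np.arange(m)

    # Gray edge i joins the positions of values 2i and 2i+1; a gray edge
    # is oriented iff its endpoint positions share parity.
    gl = pos[2 * np.arange(n + 1)]
    gr = pos[2 * np.arange(n + 1) + 1]
    left = np.minimum(gl, gr)
    right = np.maximum(gl, gr)
    oriented_edge = (gl % 2) == (gr % 2)

    # Alternating cycles: from each position, follow the black edge
    # (positions 2j <-> 2j+1) then the gray edge (values 2i <-> 2i+1).
    cycle_of_pos = np.full(m, -1, dtype=np.int64)
    n_cycles = 0
    cycle_sizes: list[int] = []
    for start in range(m):
        if cycle_of_pos[start] >= 0:
            continue
        cid = n_cycles
        n_cycles += 1
        size = 0
        p = start
        while cycle_of_pos[p] < 0:
            cycle_of_pos[p] = cid
            q = p + 1 if p % 2 == 0 else p - 1  # black partner
            cycle_of_pos[q] = cid
            size += 2
            v = s[q]
            mate = v + 1 if v % 2 == 0 else v - 1
            p = pos[mate]  # gray partner of q
        cycle_sizes.append(size)

    # Hurdle / fortress analysis is only needed when some non-trivial
    # cycle has no oriented gray edge.
    edge_cycle = cycle_of_pos[left]
    sizes = np.asarray(cycle_sizes)
    cyc_oriented = np.zeros(n_cycles, dtype=bool)
    np.logical_or.at(cyc_oriented, edge_cycle, oriented_edge)
    nontrivial = sizes > 2
    if not np.any(nontrivial & ~cyc_oriented):
        return _Graph(n, n_cycles, 0, False)

    # Connected components of the interleaving (crossing) graph over the
    # gray edges of non-trivial cycles.  Spans of distinct components are
    # laminar (nested or disjoint) by construction.
    keep = nontrivial[edge_cycle]
    li, ri, ci = left[keep], right[keep], edge_cycle[keep]
    k = li.size
    cross = (li[:, None] < li[None, :]) & (li[None, :] < ri[:, None]) \
        & (ri[:, None] < ri[None, :])
    cross = cross | cross.T
    # edges of the same cycle are trivially in one component
    same_cycle = ci[:, None] == ci[None, :]
    adj = csr_matrix(cross | same_cycle)
    n_comp, comp = connected_components(adj, directed=False)

    comp_oriented = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(comp_oriented, comp, cyc_oriented[ci])
    comp_left = np.full(n_comp, np.iinfo(np.int64).max)
    comp_right = np.zeros(n_comp, dtype=np.int64)
    np.minimum.at(comp_left, comp, li)
    np.maximum.at(comp_right, comp, ri)

    unoriented = [
        (int(comp_left[u]), int(comp_right[u]))
        for u in range(n_comp)
        if not comp_oriented[u]
    ]
    hurdle_spans = _hurdles(unoriented)
    h = len(hurdle_spans)
    f = h % 2 == 1 and h > 0 and all(
        _is_super_hurdle(span, unoriented) for span in hurdle_spans
    )
    return _Graph(n, n_cycles, h, bool(f))


def _contains(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[0] and b[1] < a[1]


def _hurdles(unoriented: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Hurdles among unoriented-component spans (a laminar family).

    A component is a hurdle iff one side of its span holds no other
    unoriented component: either it is minimal (contains none) or it is
    the greatest (contains all the others).
    """
    out = []
    for u in unoriented:
        others = [v for v in unoriented if v != u]
        inside = [v for v in others if _contains(u, v)]
        if not inside or len(inside) == len(others):
            out.append(u)
    return out


def _is_super_hurdle(h: tuple[int, int],
                     unoriented: list[tuple[int, int]]) -> bool:
    """A hurdle is *super* if removing it would promote some currently
    non-hurdle unoriented component to a hurdle."""
    before = set(_hurdles(unoriented))
    remaining = [v for v in unoriented if v != h]
    after = set(_hurdles(remaining))
    return bool(after - (before - {h}))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_linear(perm: SignedPermutation) -> tuple[int, ...]:
    if perm.circular:
        perm = perm.canonical_linear()
    return perm.elements


def inversion_distance(perm: SignedPermutation) -> int:
    """Exact minimum number of reversals sorting ``perm`` to identity.

    Circular permutations are cut at gene 1 (oriented +) first; the
    distance over the circle equals that of the cut linear permutation.
    """
    elems = _as_linear(perm)
    return _analyze(elems).distance


def breakpoint_graph_summary(perm: SignedPermutation) -> dict:
    """Cycle/hurdle/fortress decomposition behind the distance formula."""
    g = _analyze(_as_linear(perm))
    return {
        "n": g.n,
        "cycles": g.cycles,
        "hurdles": g.hurdles,
        "fortress": g.fortress,
        "distance": g.distance,
    }


def _neighbors(state: tuple[int, ...]):
    n = len(state)
    for i in range(n):
        for j in range(i, n):
            yield state[:i] + tuple(-x for x in reversed(state[i:j + 1])) \
                + state[j + 1:]


def inversion_distance_bfs(perm: SignedPermutation, cap: int | None = None) -> int:
    """Reversal distance by bidirectional breadth-first search.

    A brute-force cross-check, independent of breakpoint-graph theory.
    Practical only for small permutations (n ≤ ~7).  Raises
    ``RuntimeError`` when the distance would exceed ``cap``.
    """
    start = _as_linear(perm)
    n = len(start)
    if cap is None:
        cap = n + 1
    goal = tuple(range(1, n + 1))
    if start == goal:
        return 0
    fwd = {start: 0}
    bwd = {goal: 0}
    f_frontier, b_frontier = [start], [goal]
    d_f = d_b = 0
    best = float("inf")
    while d_f + d_b <= cap:
        if best <= d_f + d_b:  # no shorter meeting can still appear
            return int(best)
        # expand the smaller frontier one full level
        if len(f_frontier) <= len(b_frontier):
            frontier, seen, other = f_frontier, fwd, bwd
            d_f += 1
            depth = d_f
        else:
            frontier, seen, other = b_frontier, bwd, fwd
            d_b += 1
            depth = d_b
        nxt = []
        for st in frontier:
            for nb in _neighbors(st):
                if nb in seen:
                    continue
                if nb in other:
                    best = min(best, depth + other[nb])
                seen[nb] = depth
                nxt.append(nb)
        if seen is fwd:
            f_frontier = nxt
        else:
            b_frontier = nxt
        if not nxt:
            break
    if best <= cap:
        return int(best)
    raise RuntimeError(f"BFS exceeded cap={cap} reversals")
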