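"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by enumeration, exhaustive
search, or closed forms, sharing no algorithmic machinery with the
package implementations it cross-checks.
"""

from __future__ import annotations

import heapq
from collections import deque
from math import log

import numpy as np

# ---------------------------------------------------------------------------
# reversal distances
# ---------------------------------------------------------------------------


def all_reversals(state: tuple[int, ...]):
    n = len(state)
    for i in range(n):
        for j in range(i, n):
            yield state[:i] + tuple(-x for x in reversed(state[i:j + 1])) \
                + state[j + 1:]


def bfs_distance_table(n: int) -> dict[tuple[int, ...], int]:
    """Reversal distance from identity to every signed permutation of
    {1..n}, by plain breadth-first search over the whole state space."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        state = queue.popleft()
        d = dist[state]
        for nb in all_reversals(state):
            if nb not in dist:
                dist[nb] = d + 1
                queue.append(nb)
    return dist


def _cycle_lower_bound(state: tuple[int, ...]) -> int:
    """Bafna–Pevzner bound: (n+1) − cycles of the breakpoint graph.

    Standalone cycle counter (no component / hurdle analysis involved),
    admissible for A*."""
    n = len(state)
    s = [0]
    for e in state:
        s += [2 * e - 1, 2 * e] if e > 0 else [-2 * e, -2 * e - 1]
    s.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(s)}
    seen = [False] * (2 * n + 2)
    cycles = 0
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        cycles += 1
        p = start
        while not seen[p]:
            seen[p] = True
            q = p + 1 if p % 2 == 0 else p - 1
            seen[q] = True
            v = s[q]
            p = pos[v + 1 if v % 2 == 0 else v - 1]
    return (n + 1) - cycles


def astar_reversal_distance(state: tuple[int, ...]) -> int:
    """Exact reversal distance by A* over reversal moves with the cycle
    lower bound — an optimal search, independent of hurdle theory."""
    n = len(state)
    goal = tuple(range(1, n + 1))
    g = {state: 0}
    heap = [(_cycle_lower_bound(state), state)]
    while heap:
        f, st = heapq.heappop(heap)
        if st == goal:
            return g[st]
        gs = g[st]
        if f > gs + _cycle_lower_bound(st):
            continue
        for nb in all_reversals(st):
            ng = gs + 1
            if nb not in g or ng < g[nb]:
                g[nb] = ng
                heapq.heappush(heap, (ng + _cycle_lower_bound(nb), nb))
    raise RuntimeError("unreachable goal")


# ---------------------------------------------------------------------------
# adjacency / GOC
# ---------------------------------------------------------------------------


def goc_by_enumeration(perm: tuple[int, ...], circular: bool = True) -> float:
    """GOC by explicit adjacency-set comparison."""
    n = len(perm)
    labels = [abs(e) for e in perm]

    def adjacencies(seq):
        pairs = {frozenset((seq[i], seq[i + 1])) for i in range(len(seq) - 1)}
        if circular and len(seq) > 1:
            pairs.add(frozenset((seq[-1], seq[0])))
        return pairs

    ref = adjacencies(list(range(1, n + 1)))
    obs = adjacencies(labels)
    return len(ref & obs) / n


# ---------------------------------------------------------------------------
# repeats and MUMs
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_direct_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal direct repeat pairs (pos1, pos2, length) by checking
    every position pair."""
    n = len(seq)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j]:
                continue
            if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal
            L = 0
            while i + L < n and j + L < n and seq[i + L] == seq[j + L]:
                L += 1
            if L >= min_len:
                out.add((i, j, L))
    return out


def brute_force_inverted_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal inverted (reverse-complement) repeat pairs with
    disjoint copies: seq[j:j+L] == revcomp(seq[i:i+L]), i + L <= j,
    maximal under the two extensions that preserve disjointness."""
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            for L in range(min_len, min(n - j, j - i) + 1):
                if seq[j:j + L] != revcomp(seq[i:i + L]):
                    continue
                # maximality: copy1-right/copy2-left extension
                ext1 = (j - 1 >= i + L) and j > 0 and i + L < n and \
                    seq[j - 1] == comp[seq[i + L]]
                # copy1-left/copy2-right extension
                ext2 = i > 0 and j + L < n and seq[j + L] == comp[seq[i - 1]]
                if not ext1 and not ext2:
                    out.add((i, j, L))
    return out


def brute_force_mums(ref: str, qry: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal unique matches by quadratic enumeration.

    Uniqueness: the substring occurs once in the forward reference and
    once in the query counting both strands."""
    qrc = revcomp(qry)
    out = set()
    for strand, q in (("forward", qry), ("reverse", qrc)):
        for i in range(len(ref)):
            for j in range(len(q)):
                if ref[i] != q[j]:
                    continue
                if i > 0 and j > 0 and ref[i - 1] == q[j - 1]:
                    continue
                L = 0
                while i + L < len(ref) and j + L < len(q) and ref[i + L] == q[j + L]:
                    L += 1
                if L < min_len:
                    continue
                sub = ref[i:i + L]
                if count_occurrences(ref, sub) != 1:
                    continue
                if count_occurrences(qry, sub) + count_occurrences(qrc, sub) != 1:
                    continue
                qpos = j if strand == "forward" else len(qry) - j - L
                out.add((i, qpos, L, strand))
    return out


def count_occurrences(text: str, pat: str) -> int:
    count = start = 0
    while True:
        hit = text.find(pat, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1


def longest_repeat_length(arr: np.ndarray, rng: np.random.Generator,
                          lo: int = 8, hi: int = 40) -> int:
    """Longest repeated substring length of an integer-coded sequence,
    by binary search over rolling-hash duplicate detection."""
    base = np.uint64(1099511628211)

    def has_duplicate(L: int) -> bool:
        powers = np.empty(L, dtype=np.uint64)
        powers[0] = np.uint64(1)
        with np.errstate(over="ignore"):  # hashes live mod 2^64
            for t in range(1, L):
                powers[t] = powers[t - 1] * base
            windows = np.lib.stride_tricks.sliding_window_view(
                arr.astype(np.uint64), L)
            hashes = windows @ powers
        uniq, counts = np.unique(hashes, return_counts=True)
        if not (counts > 1).any():
            return False
        # verify one duplicate against the raw sequence (hash safety)
        dup_hash = uniq[counts > 1][0]
        pos = np.flatnonzero(hashes == dup_hash)[:2]
        return bool(np.array_equal(arr[pos[0]:pos[0] + L],
                                   arr[pos[1]:pos[1] + L]))

    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has_duplicate(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def jukes_cantor_distance(diff_fraction: float) -> float:
    return -0.75 * log(1.0 - 4.0 * diff_fraction / 3.0)


def percentile_interval(samples: np.ndarray, alpha: float = 0.05):
    return (float(np.quantile(samples, alpha / 2)),
            float(np.quantile(samples, 1 - alpha / 2)))
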