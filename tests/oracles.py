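"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the problem definitions rather
than by calling the package: nested-pairing maximization by leftmost-position
recursion, affine alignment by memoized three-state recursion over all
monotone alignments, a literal per-column profile recount, and additive
(tree) metrics built from explicit random trees.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def brute_pair_count(seq: str) -> int:
    """Maximum nested pairing (min loop 3) by enumeration over the first position."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        top = best(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            if seq[i] + seq[k] in _PAIRS:
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1) if seq else 0


def brute_align_score(a: str, b: str, match: float, mismatch: float,
                      gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score over all monotone alignments."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state 0: last column was a match/mismatch (or start)
        # state 1: gap in b (consumed a); state 2: gap in a (consumed b)
        if i == len(a) and j == len(b):
            return 0.0
        out = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            out = max(out, s + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            out = max(out, -cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            out = max(out, -cost + best(i, j + 1, 2))
        return out

    return best(0, 0, 0)


def naive_profile(rows: dict[str, str], projections: dict[str, list[int]],
                  min_occupancy: float = 0.5):
    """Literal recount of the per-position divergence profile.

    Builds an explicit symbol matrix over the union of projected columns
    ('' = outside the row's strand region, '-' = internal gap), then tallies
    column by column.  Returns (consensus, subst, indel, effective_n) lists.
    """
    ids = list(projections)
    union = sorted({c for cols in projections.values() for c in cols})
    matrix: dict[str, dict[int, str]] = {}
    for rid in ids:
        cols = projections[rid]
        lo, hi = min(cols), max(cols)
        colset = set(cols)
        symbols = {}
        for c in union:
            if c < lo or c > hi:
                symbols[c] = ""
            elif c in colset:
                symbols[c] = rows[rid][c - 1]
            else:
                symbols[c] = "-"
        matrix[rid] = symbols
    kept = []
    for c in union:
        n_res = sum(1 for rid in ids if matrix[rid][c] not in ("", "-"))
        if n_res >= min_occupancy * len(ids):
            kept.append(c)
    consensus, subst, indel, eff = [], [], [], []
    for c in kept:
        syms = [matrix[rid][c] for rid in ids if matrix[rid][c] != ""]
        residues = [s for s in syms if s != "-"]
        gaps = len(syms) - len(residues)
        order = "ACGU"
        counts = {b: residues.count(b) for b in set(residues)}
        ref = sorted(counts, key=lambda b: (-counts[b], order.index(b)))[0]
        consensus.append(ref)
        subst.append((len(residues) - counts[ref]) / len(syms))
        indel.append(gaps / len(syms))
        eff.append(len(syms))
    return kept, consensus, subst, indel, eff


def random_tree_metric(rng: np.random.Generator, n: int):
    """Random binary tree over n leaves -> (distance matrix, split weights).

    Splits are keyed by the side not containing leaf 0; pendant and internal
    edges all get lengths in [0.2, 2.0].
    """
    # adjacency with weights; internal nodes numbered from n upward
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        adj[nxt] = {}
        for leafish in (a, b):
            w = float(rng.uniform(0.2, 2.0))
            adj[leafish][nxt] = w
            adj[nxt][leafish] = w
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    def dijkstra(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        frontier = [(0.0, src)]
        import heapq

        while frontier:
            d0, u = heapq.heappop(frontier)
            if d0 > dist.get(u, math.inf):
                continue
            for v, w in adj[u].items():
                nd = d0 + w
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(frontier, (nd, v))
        return dist

    D = np.zeros((n, n))
    for p in range(n):
        dd = dijkstra(p)
        for q in range(n):
            D[p, q] = dd[q]

    splits: dict[frozenset[int], float] = {}
    for u in adj:
        for v, w in adj[u].items():
            if u > v:
                continue
            # leaves on u's side after removing edge (u, v)
            seen = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y in seen or {x, y} == {u, v}:
                        continue
                    seen.add(y)
                    stack.append(y)
            side = frozenset(x for x in seen if x < n)
            if 0 < len(side) < n:
                if 0 in side:
                    side = frozenset(range(n)) - side
                splits[side] = splits.get(side, 0.0) + w
    return D, splits
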