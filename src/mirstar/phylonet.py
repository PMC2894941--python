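"""Jukes-Cantor distances and neighbor-net split networks.

Distances use the one-parameter Jukes-Cantor correction
``d = -(3/4) ln(1 - 4p/3)`` after complete deletion (every column containing
a gap in any row is removed).  The network side implements the agglomerative
neighbor-net construction of a circular taxon ordering - NJ-style cluster
selection, a second node-level selection, and 3-point reductions - followed
by a least-squares fit of the full circular split system with non-negativity
enforced by iteratively dropping negative-weight splits and refitting.
Networks serialize to NEXUS with TAXA and SPLITS blocks readable by
SplitsTree-style viewers (and by this module's own reader).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedDistanceError
from .family_msa import Alignment

#: p-distances at or above this are capped (the JC transform diverges at 3/4)
SATURATION_CAP = 0.74


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction of a proportion of differing sites."""
    if not 0 <= p < 0.75:
        raise ValueError(f"p={p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_matrix(alignment: Alignment, cap: float = SATURATION_CAP) -> DistanceMatrix:
    """JC distance matrix from a gapped alignment, complete deletion."""
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    rows = alignment.rows
    keep = [c for c in range(alignment.ncol) if all(r[c] != "-" for r in rows)]
    if not keep:
        raise UndefinedDistanceError("no gap-free columns remain after complete deletion")
    stripped = ["".join(r[c] for c in keep) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    warns = []
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(1 for x, y in zip(stripped[i], stripped[j]) if x != y)
            p = diff / len(keep)
            if p >= cap:
                warns.append(
                    f"saturated p={p:.4f} between {alignment.row_ids[i]!r} and "
                    f"{alignment.row_ids[j]!r}; capped at {cap}"
                )
                p = cap
            d[i, j] = d[j, i] = jc_distance(p)
    return DistanceMatrix(list(alignment.row_ids), d, warns)


@dataclass
class SplitNetwork:
    """A circular split system: ordering plus weighted interval bipartitions.

    Each split is stored as the side not containing the first taxon of the
    circular order, as a frozenset of taxon labels.
    """

    taxa: list[str]
    circular_order: list[str]
    splits: list[tuple[frozenset[str], float]]
    ls_residual: float = 0.0

    def separated(self, side: frozenset[str], a: str, b: str) -> bool:
        return (a in side) != (b in side)


# ---------------------------------------------------------------------------
# circular ordering (neighbor-net agglomeration)

def _neighbor_net_order(D: np.ndarray) -> list[int]:
    n = len(D)
    if n <= 3:
        return list(range(n))
    dist: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []
    next_id = n

    def d(a: int, b: int) -> float:
        return dist[a][b]

    def cdist(A: Sequence[int], B: Sequence[int]) -> float:
        return sum(d(a, b) for a in A for b in B) / (len(A) * len(B))

    total_nodes = n
    while total_nodes > 3 and len(clusters) > 1:
        m = len(clusters)
        # --- first selection: pair of clusters by the NJ criterion
        if m == 2:
            bi, bj = 0, 1
        else:
            cd = [[0.0] * m for _ in range(m)]
            for i in range(m):
                for j in range(i + 1, m):
                    cd[i][j] = cd[j][i] = cdist(clusters[i], clusters[j])
            R = [sum(cd[i][k] for k in range(m) if k != i) for i in range(m)]
            best = None
            bi = bj = 0
            for i in range(m):
                for j in range(i + 1, m):
                    q = (m - 2) * cd[i][j] - R[i] - R[j]
                    if best is None or q < best:
                        best, bi, bj = q, i, j
        A, B = clusters[bi], clusters[bj]
        # --- second selection: node pair, nodes of A and B counted singly
        if len(A) == 1 and len(B) == 1:
            x, y = A[0], B[0]
        else:
            units = [clusters[k] for k in range(len(clusters)) if k not in (bi, bj)]
            units += [[z] for z in A + B]
            mhat = len(units)

            def udist(node: int, unit: Sequence[int]) -> float:
                return sum(d(node, z) for z in unit) / len(unit)

            best = None
            x = y = -1
            for xa in A:
                rx = sum(udist(xa, u) for u in units if u != [xa])
                for yb in B:
                    ry = sum(udist(yb, u) for u in units if u != [yb])
                    q = (mhat - 2) * d(xa, yb) - rx - ry
                    if best is None or q < best:
                        best, x, y = q, xa, yb
        # --- link x (endpoint of A) to y (endpoint of B)
        cA = list(A) if A[-1] == x else list(reversed(A))
        cB = list(B) if B[0] == y else list(reversed(B))
        chain = cA + cB
        rest = [c for k, c in enumerate(clusters) if k not in (bi, bj)]
        while len(chain) > 2:
            c1, c2, c3 = chain[0], chain[1], chain[2]
            u, v = next_id, next_id + 1
            next_id += 2
            others = [w for grp in rest for w in grp] + chain[3:]
            dist[u] = {}
            dist[v] = {}
            for w in others:
                duw = (2.0 * d(c1, w) + d(c2, w)) / 3.0
                dvw = (2.0 * d(c3, w) + d(c2, w)) / 3.0
                dist[u][w] = duw
                dist[w][u] = duw
                dist[v][w] = dvw
                dist[w][v] = dvw
            duv = (d(c1, c2) + d(c2, c3) + d(c1, c3)) / 3.0
            dist[u][v] = duv
            dist[v][u] = duv
            reductions.append((u, v, c1, c2, c3))
            chain = [u, v] + chain[3:]
            for w in others:
                dist[w][u] = dist[u][w]
                dist[w][v] = dist[v][w]
        clusters = rest + [chain]
        total_nodes = sum(len(c) for c in clusters)

    order = [node for chain in clusters for node in chain]
    # expand reductions in reverse to recover the original taxa
    for u, v, c1, c2, c3 in reversed(reductions):
        i = order.index(u)
        order = order[i:] + order[:i]  # rotate u to front
        if len(order) > 1 and order[1] == v:
            order = [c1, c2, c3] + order[2:]
        elif order[-1] == v:
            order = [c1] + order[1:-1] + [c3, c2]
        else:  # pragma: no cover - adjacency is guaranteed by construction
            raise RuntimeError("reduction pair not adjacent in circular order")
    return order


def _interval_splits(order_idx: Sequence[int], n: int) -> list[frozenset[int]]:
    """The full circular split system: n(n-1)/2 interval bipartitions."""
    splits = []
    for a in range(1, n):
        for b in range(a, n):
            splits.append(frozenset(order_idx[a : b + 1]))
    return splits


def neighbor_net(D: DistanceMatrix, weight_floor: float = 1e-8) -> SplitNetwork:
    """Build a split network from a distance matrix.

    Split weights come from an ordinary least-squares fit over the circular
    split system; negative-weight splits are removed and the system refit
    until all weights are non-negative (a deterministic approximation to a
    constrained NNLS, adequate at gene-family scale).
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    order_idx = _neighbor_net_order(D.values)
    order = [D.taxa[i] for i in order_idx]
    splits_idx = _interval_splits(order_idx, n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dvec = np.array([D.values[i, j] for i, j in pairs])
    A = np.zeros((len(pairs), len(splits_idx)))
    for col, side in enumerate(splits_idx):
        for row, (i, j) in enumerate(pairs):
            if (i in side) != (j in side):
                A[row, col] = 1.0
    active = list(range(len(splits_idx)))
    w = np.zeros(0)
    while True:
        w, *_ = np.linalg.lstsq(A[:, active], dvec, rcond=None)
        neg = w < -1e-12
        if not neg.any():
            break
        active = [s for s, bad in zip(active, neg) if not bad]
        if not active:
            w = np.zeros(0)
            break
    residual = float(np.linalg.norm(A[:, active] @ w - dvec)) if active else float(
        np.linalg.norm(dvec)
    )
    splits = [
        (frozenset(D.taxa[i] for i in splits_idx[s]), float(wt))
        for s, wt in zip(active, w)
        if wt >= weight_floor
    ]
    return SplitNetwork(list(D.taxa), order, splits, residual)


def realized_distance(network: SplitNetwork, a: str, b: str) -> float:
    """Distance induced by the network: sum of separating split weights."""
    if a not in network.taxa or b not in network.taxa:
        raise KeyError(f"unknown taxon among {a!r}, {b!r}")
    return sum(w for side, w in network.splits if network.separated(side, a, b))


# ---------------------------------------------------------------------------
# NEXUS SPLITS I/O

def write_nexus(network: SplitNetwork, path: str | Path) -> None:
    taxa = network.taxa
    index = {t: k + 1 for k, t in enumerate(taxa)}
    lines = ["#NEXUS", "", "BEGIN Taxa;", f"DIMENSIONS ntax={len(taxa)};", "TAXLABELS"]
    lines += [f"[{k + 1}] '{t}'" for k, t in enumerate(taxa)]
    lines += [";", "END;", "", "BEGIN Splits;"]
    lines.append(f"DIMENSIONS ntax={len(taxa)} nsplits={len(network.splits)};")
    lines.append("FORMAT labels=no weights=yes confidences=no intervals=no;")
    lines.append("CYCLE " + " ".join(str(index[t]) for t in network.circular_order) + ";")
    lines.append("MATRIX")
    for k, (side, w) in enumerate(network.splits, start=1):
        members = " ".join(str(index[t]) for t in sorted(side, key=lambda t: index[t]))
        lines.append(f"[{k}] {w:.17g} {members},")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus(path: str | Path) -> SplitNetwork:
    text = Path(path).read_text()
    tax_block = re.search(r"TAXLABELS(.*?);", text, re.S | re.I).group(1)
    taxa = re.findall(r"'([^']*)'", tax_block)
    cycle = re.search(r"CYCLE([^;]*);", text, re.I).group(1).split()
    order = [taxa[int(k) - 1] for k in cycle]
    matrix = re.search(r"MATRIX(.*?);", text, re.S | re.I).group(1)
    splits: list[tuple[frozenset[str], float]] = []
    for line in matrix.strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        line = re.sub(r"^\[\d+\]\s*", "", line)
        fields = line.split()
        weight = float(fields[0])
        side = frozenset(taxa[int(k) - 1] for k in fields[1:])
        splits.append((side, weight))
    return SplitNetwork(taxa, order, splits)


def write_distances(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, sep="\t", float_format="%.6f")
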