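"""Progressive multiple alignment of miRNA gene-family members.

A self-contained Needleman-Wunsch/Gotoh pairwise aligner with affine gap
costs, a UPGMA guide tree built from pairwise p-distances, and sum-of-pairs
profile-profile alignment up the tree.  All tie-breaks are deterministic
(traceback prefers diagonal, then up, then left; agglomeration ties break on
the lexicographically smallest id pair) so outputs are bit-stable.

This is deliberately not a Clustal re-implementation: no sequence weighting,
no position-specific gap penalties.  For ~60-120 nt hairpin families the
simple scheme recovers the stem/loop correspondence that downstream
profiling needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import mirbase_io
from .errors import MirstarError, UndefinedDistanceError

_NEG = -1.0e30


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring: a gap of length k costs ``gap_open + k*gap_extend``."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not self.match > self.mismatch:
            raise ValueError("require match > mismatch")

    def score(self, x: str, y: str) -> float:
        return self.match if x == y else self.mismatch


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    """Gapped rows over {A,C,G,U,-}; all rows the same length."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def write_fasta(self, path: str | Path) -> None:
        mirbase_io.write_fasta(zip(self.row_ids, self.rows), path)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        recs = mirbase_io.read_fasta(path, allow_gap=True)
        return cls([r.id for r in recs], [r.sequence for r in recs])


# ---------------------------------------------------------------------------
# pairwise alignment (Gotoh)

def _gotoh(n: int, m: int, sub: Callable[[int, int], float], params: AlignParams):
    """Affine-gap DP over an n x m problem; returns (ops, score).

    ops is a string over D (diagonal), U (up: consume row item against a
    gap), L (left).  State tie-breaks prefer M, then U(X), then L(Y), which
    realizes the "diagonal, up, left" traceback preference.
    """
    go, ge = params.gap_open, params.gap_extend
    open_cost = go + ge
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # ends consuming a row item (up)
    Y = np.full((n + 1, m + 1), _NEG)  # ends consuming a column item (left)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
        ptr_x[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)
        ptr_y[0, j] = 2

    def argbest(vm, vx, vy):
        # deterministic preference M > X > Y on ties
        if vm >= vx and vm >= vy:
            return 0, vm
        if vx >= vy:
            return 1, vx
        return 2, vy

    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = sub(i - 1, j - 1)
            k, v = argbest(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = v + s
            ptr_m[i, j] = k
            k, v = argbest(Mi1[j] - open_cost, Xi1[j] - ge, Yi1[j] - open_cost)
            Xi[j] = v
            ptr_x[i, j] = k
            k, v = argbest(Mi[j - 1] - open_cost, Xi[j - 1] - open_cost, Yi[j - 1] - ge)
            Yi[j] = v
            ptr_y[i, j] = k

    state, score = argbest(M[n, m], X[n, m], Y[n, m])
    ops = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            state = ptr_x[i, j]
            i -= 1
        else:
            ops.append("L")
            state = ptr_y[i, j]
            j -= 1
    return "".join(reversed(ops)), float(score)


def nw_align(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gap costs."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ops, score = _gotoh(len(a), len(b), lambda i, j: params.score(a[i], b[j]), params)
    ga, gb = [], []
    i = j = 0
    for op in ops:
        if op == "D":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ga.append(a[i]); gb.append("-"); i += 1
        else:
            ga.append("-"); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb), score


def p_distance(gapped_a: str, gapped_b: str) -> float:
    """Proportion of differing sites, complete-deletion of gapped columns."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("rows must have equal length")
    total = diff = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            diff += 1
    if total == 0:
        raise UndefinedDistanceError("no ungapped columns shared by the two rows")
    return diff / total


# ---------------------------------------------------------------------------
# UPGMA guide tree

@dataclass
class TreeNode:
    rep: str  # lexicographically smallest leaf id in the clade
    height: float = 0.0
    children: tuple = ()
    leaf_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_id]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def guide_tree(ids: Sequence[str], dmat: np.ndarray) -> TreeNode:
    """UPGMA (average linkage) tree; deterministic lexicographic tie-breaks."""
    dmat = np.asarray(dmat, dtype=float)
    if dmat.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(dmat, dmat.T) or not np.allclose(np.diag(dmat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(rep=i, leaf_id=i) for i in ids]
    sizes = [1] * len(ids)
    dist = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(i, j)] = dmat[i, j]
    active = list(range(len(ids)))
    next_idx = len(ids)
    store: dict[int, TreeNode] = {i: n for i, n in enumerate(nodes)}
    size: dict[int, int] = {i: s for i, s in enumerate(sizes)}

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = get(i, j)
                pair_key = tuple(sorted((store[i].rep, store[j].rep)))
                cand = (d, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, i, j = best
        ci, cj = store[i], store[j]
        left, right = (ci, cj) if ci.rep <= cj.rep else (cj, ci)
        parent = TreeNode(rep=min(ci.rep, cj.rep), height=d / 2.0, children=(left, right))
        store[next_idx] = parent
        size[next_idx] = size[i] + size[j]
        for k in active:
            if k in (i, j):
                continue
            dnew = (size[i] * get(i, k) + size[j] * get(j, k)) / (size[i] + size[j])
            dist[(min(k, next_idx), max(k, next_idx))] = dnew
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1
    return store[active[0]]


# ---------------------------------------------------------------------------
# progressive profile alignment

def _profile_columns(rows: list[str]):
    """Per-column residue counts (gaps excluded) for sum-of-pairs scoring."""
    ncol = len(rows[0])
    cols = []
    for c in range(ncol):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[c]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        cols.append(counts)
    return cols


def _align_profiles(rows_a: list[str], rows_b: list[str], params: AlignParams):
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    na, nb = len(rows_a), len(rows_b)
    denom = float(na * nb)
    match, mismatch = params.match, params.mismatch

    def sub(i: int, j: int) -> float:
        total = 0.0
        ca, cb = cols_a[i], cols_b[j]
        for x, nx in ca.items():
            for y, ny in cb.items():
                total += nx * ny * (match if x == y else mismatch)
        return total / denom  # residue-vs-gap and gap-vs-gap score 0

    ops, _ = _gotoh(len(cols_a), len(cols_b), sub, params)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            i += 1; j += 1
        elif op == "U":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            j += 1
    return out_a, out_b


def progressive_align(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    params: AlignParams = DEFAULT_PARAMS,
) -> Alignment:
    """Align >=2 sequences progressively up a UPGMA guide tree."""
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    ids = [i for i, _ in items]
    seqs = dict(items)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    n = len(ids)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = nw_align(seqs[ids[i]], seqs[ids[j]], params)
            dmat[i, j] = dmat[j, i] = p_distance(ga, gb)
    tree = guide_tree(ids, dmat)

    def build(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.leaf_id], [seqs[node.leaf_id]]
        (ids_l, rows_l) = build(node.children[0])
        (ids_r, rows_r) = build(node.children[1])
        rows_l, rows_r = _align_profiles(rows_l, rows_r, params)
        return ids_l + ids_r, rows_l + rows_r

    out_ids, out_rows = build(tree)
    # drop all-gap columns (cannot normally arise, but keep the invariant)
    keep = [c for c in range(len(out_rows[0])) if any(r[c] != "-" for r in out_rows)]
    if len(keep) != len(out_rows[0]):
        out_rows = ["".join(r[c] for c in keep) for r in out_rows]
    aln = Alignment(out_ids, out_rows)
    for rid in ids:
        if aln.ungapped(rid) != seqs[rid]:
            raise MirstarError(f"alignment corrupted row {rid!r}")  # pragma: no cover
    return aln


def project_span(alignment: Alignment, row_id: str, span: tuple[int, int]) -> list[int]:
    """Columns (1-based) occupied by residues ``start..end`` of a row."""
    start, end = span
    row = alignment.row(row_id)
    if start < 1 or start > end:
        raise ValueError(f"invalid span {span}")
    cols = []
    residue = 0
    for c, ch in enumerate(row, start=1):
        if ch == "-":
            continue
        residue += 1
        if start <= residue <= end:
            cols.append(c)
        if residue >= end:
            break
    if residue < end:
        raise ValueError(f"span {span} exceeds ungapped length {residue} of row {row_id!r}")
    return cols
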