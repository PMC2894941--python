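"""Hairpin secondary structure and miRNA* (star) span inference.

The passenger strand of a Dicer duplex sits on the opposite arm of the
hairpin, base-paired to the mature strand and offset so that both duplex
ends carry 2-nt 3' overhangs.  Given a nested maximum-pairing fold of the
precursor this geometry determines the star span from the mature span:

    5'-arm mature (s, e):  star = (P(e-2), P(s) + 2)
    3'-arm mature (s, e):  star = (P(e) - 2, P(s + 2))

where P is the pairing map, extended across small interior bulges by
scanning (at most 3 nt) to the nearest paired base.  When a homologous
precursor with a known star is available, the span is instead transferred
through a pairwise alignment, which is the preferred route.

Folding is plain base-pair maximization (Nussinov) with Watson-Crick plus
G-U wobble pairs and a minimum hairpin loop of 3 - a deliberate
simplification adequate for canonical miRNA stem-loops; no free-energy
model is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    SpanInconsistencyError,
    StructureTooWeakError,
    TransferFailedError,
    UnpairedEndpointError,
)
from .family_msa import AlignParams, DEFAULT_PARAMS, nw_align

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
MIN_LOOP = 3  # unpaired bases enclosed by any pair
_BULGE_REACH = 3  # how far a duplex endpoint may scan for a paired base


@dataclass(frozen=True)
class PairMap:
    """A nested (pseudoknot-free) pairing over positions 1..length."""

    length: int
    pairs: dict[int, int]  # symmetric: pairs[i] == j implies pairs[j] == i

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def dot_bracket(self) -> str:
        out = ["."] * self.length
        for i, j in self.pairs.items():
            if i < j:
                out[i - 1] = "("
                out[j - 1] = ")"
        return "".join(out)


@dataclass(frozen=True)
class StarCall:
    """An inferred passenger-strand span on a hairpin."""

    hairpin_id: str
    span: tuple[int, int]
    method: str  # reported | transfer | duplex
    confidence_note: str = ""


def _can_pair(x: str, y: str) -> bool:
    return x + y in CANONICAL_PAIRS


def fold_nussinov(sequence: str) -> PairMap:
    """Maximum base-pairing nested fold with deterministic traceback.

    Traceback prefers pairing (i, j) over bifurcation and takes the smallest
    split point first, so equal-scoring structures resolve identically.
    """
    seq = sequence
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    F = np.zeros((n + 2, n + 2), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = max(F[i + 1, j], F[i, j - 1])
            if _can_pair(seq[i - 1], seq[j - 1]):
                best = max(best, F[i + 1, j - 1] + 1)
            for k in range(i + 1, j):
                cand = F[i, k] + F[k + 1, j]
                if cand > best:
                    best = cand
            F[i, j] = best
    pairs: dict[int, int] = {}
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        if i >= j or F[i, j] == 0:
            continue
        if (
            _can_pair(seq[i - 1], seq[j - 1])
            and j - i >= MIN_LOOP + 1
            and F[i, j] == F[i + 1, j - 1] + 1
        ):
            pairs[i] = j
            pairs[j] = i
            stack.append((i + 1, j - 1))
        elif F[i, j] == F[i + 1, j]:
            stack.append((i + 1, j))
        elif F[i, j] == F[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if F[i, k] + F[k + 1, j] == F[i, j]:
                    stack.append((k + 1, j))
                    stack.append((i, k))
                    break
    return PairMap(n, pairs)


def _extended_partner(pm: PairMap, x: int) -> int:
    """P extended across bulges: offset from the nearest paired base (<=3 nt)."""
    if pm.partner(x) is not None:
        return pm.partner(x)
    for d in range(1, _BULGE_REACH + 1):
        for x2 in (x - d, x + d):
            if 1 <= x2 <= pm.length and pm.partner(x2) is not None:
                return pm.partner(x2) + (x2 - x)
    raise UnpairedEndpointError(
        f"no paired base within {_BULGE_REACH} nt of position {x}"
    )


def infer_star_duplex(
    hairpin_id: str,
    pairmap: PairMap,
    mature_span: tuple[int, int],
) -> StarCall:
    """Place the star strand by the duplex 2-nt 3'-overhang rule."""
    s, e = mature_span
    if not (1 <= s <= e <= pairmap.length):
        raise ValueError(f"mature span {mature_span} outside hairpin 1..{pairmap.length}")
    paired = [p for p in range(s, e + 1) if pairmap.partner(p) is not None]
    if len(paired) < 0.5 * (e - s + 1):
        raise StructureTooWeakError(
            f"{hairpin_id}: only {len(paired)}/{e - s + 1} mature positions paired"
        )
    partners = [pairmap.partner(p) for p in paired]
    on_five_prime_arm = float(np.median(partners)) > e
    notes = []
    if on_five_prime_arm:
        star_start = _extended_partner(pairmap, e - 2)
        star_end = _extended_partner(pairmap, s) + 2
    else:
        star_start = _extended_partner(pairmap, e) - 2
        star_end = _extended_partner(pairmap, s + 2)
    if star_start < 1:
        notes.append(f"start clamped {star_start}->1")
        star_start = 1
    if star_end > pairmap.length:
        notes.append(f"end clamped {star_end}->{pairmap.length}")
        star_end = pairmap.length
    if star_start > star_end:
        raise SpanInconsistencyError(
            f"{hairpin_id}: degenerate star span ({star_start},{star_end})"
        )
    if not (star_end < s or star_start > e):
        raise SpanInconsistencyError(
            f"{hairpin_id}: star span ({star_start},{star_end}) overlaps mature {mature_span}"
        )
    return StarCall(hairpin_id, (star_start, star_end), "duplex", "; ".join(notes))


def infer_star_transfer(
    target_id: str,
    target_sequence: str,
    ref_sequence: str,
    ref_star_span: tuple[int, int],
    params: AlignParams = DEFAULT_PARAMS,
    min_length: int = 15,
) -> StarCall:
    """Transfer a known star span from a homologous precursor.

    The two hairpins are globally aligned; span endpoints map through the
    alignment, sliding inward past columns where the target is gapped.
    """
    rs, re_ = ref_star_span
    if not (1 <= rs <= re_ <= len(ref_sequence)):
        raise ValueError(f"reference star span {ref_star_span} invalid")
    g_ref, g_tgt, _ = nw_align(ref_sequence, target_sequence, params)
    ref_cols = [c for c, ch in enumerate(g_ref) if ch != "-"]  # residue -> column
    col_lo = ref_cols[rs - 1]
    col_hi = ref_cols[re_ - 1]
    # target residue index at or after / at or before a column
    tgt_residue = np.cumsum([1 if ch != "-" else 0 for ch in g_tgt])
    start = None
    for c in range(col_lo, col_hi + 1):
        if g_tgt[c] != "-":
            start = int(tgt_residue[c])
            break
    end = None
    for c in range(col_hi, col_lo - 1, -1):
        if g_tgt[c] != "-":
            end = int(tgt_residue[c])
            break
    if start is None or end is None or end - start + 1 < min_length:
        raise TransferFailedError(
            f"{target_id}: transferred span "
            f"{'empty' if start is None else (start, end)} shorter than {min_length} nt"
        )
    return StarCall(target_id, (start, end), "transfer", "")


def loop_span(
    mature_span: tuple[int, int], star_span: tuple[int, int]
) -> tuple[int, int]:
    """Terminal-loop interval strictly between the two duplex strands.

    A zero-length loop (adjacent strands) is returned as (start, start-1).
    """
    a, b = sorted([mature_span, star_span])
    if a[1] >= b[0]:
        raise SpanInconsistencyError(f"strand spans {mature_span} and {star_span} overlap")
    return (a[1] + 1, b[0] - 1)
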