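"""Per-position substitution profiles and strand conservation calls.

For each strand (mature, star, terminal loop) of an aligned gene family the
profile reports, at every strand-local position 1..L, the most abundant
nucleotide (the consensus reference), the fraction of counted rows that
substitute it, and the fraction carrying an internal indel.  Leading and
trailing gaps of a row's strand region are treated as missing termini and
excluded from the counts, mirroring how isomiR-style ragged ends are ignored
when only internal substitutions are of interest.

Strand-local positions arise by projecting each row's hairpin-local span
into alignment columns, keeping columns with at least 50% residue occupancy
and renumbering them 1..L; the seed is positions 2-8 and the anchor 13-16 of
the renumbered strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyProfileError, RegionError
from .family_msa import Alignment

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class RegionSpec:
    """A named set of strand-local 1-based positions."""

    name: str
    positions: tuple[int, ...]

    def __post_init__(self):
        if not self.positions:
            raise ValueError("region has no positions")


SEED = RegionSpec("seed", tuple(range(2, 9)))
ANCHOR = RegionSpec("anchor", tuple(range(13, 17)))


def full_region(length: int) -> RegionSpec:
    return RegionSpec("full", tuple(range(1, length + 1)))


@dataclass
class DivergenceProfile:
    """Per-position consensus/substitution/indel summary of one strand."""

    strand_label: str
    columns: list[int]  # original alignment columns retained
    consensus: list[str]
    subst_fraction: np.ndarray
    indel_fraction: np.ndarray
    effective_n: np.ndarray

    @property
    def length(self) -> int:
        return len(self.columns)

    @property
    def mean_subst(self) -> float:
        return float(np.mean(self.subst_fraction))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strand_label": self.strand_label,
                "position": np.arange(1, self.length + 1),
                "alignment_column": self.columns,
                "consensus": self.consensus,
                "effective_n": self.effective_n,
                "subst_fraction": self.subst_fraction,
                "indel_fraction": self.indel_fraction,
            }
        )


@dataclass(frozen=True)
class ConservationCall:
    strand_label: str
    seed_conserved: bool
    anchor_conserved: bool
    mean_subst: float
    category: str  # mature-like-conserved | diverged
    thresholds_used: tuple[float, float]


def strand_profile(
    alignment: Alignment,
    rows_to_columns: Mapping[str, Sequence[int]],
    strand_label: str = "strand",
    min_occupancy: float = 0.5,
) -> DivergenceProfile:
    """Profile one strand across family members.

    ``rows_to_columns`` gives, per row, the ordered alignment columns holding
    that row's strand residues (see :func:`mirstar.family_msa.project_span`).
    """
    row_ids = list(rows_to_columns)
    if len(row_ids) < 2:
        raise ValueError("a profile needs at least 2 rows")
    col_sets = {r: frozenset(rows_to_columns[r]) for r in row_ids}
    bounds = {r: (min(col_sets[r]), max(col_sets[r])) for r in row_ids}
    union_cols = sorted(set().union(*col_sets.values()))

    def symbol(r: str, c: int) -> str:
        """Residue, '-' for an internal gap, or '' outside the strand region."""
        lo, hi = bounds[r]
        if c < lo or c > hi:
            return ""
        if c in col_sets[r]:
            return alignment.row(r)[c - 1]
        return "-"

    kept = [
        c
        for c in union_cols
        if sum(1 for r in row_ids if symbol(r, c) not in ("", "-")) >= min_occupancy * len(row_ids)
    ]
    if not kept:
        raise EmptyProfileError(f"{strand_label}: no positions pass the occupancy filter")

    consensus, subst, indel, eff = [], [], [], []
    for c in kept:
        counts: dict[str, int] = {}
        n_indel = 0
        n_eff = 0
        for r in row_ids:
            sym = symbol(r, c)
            if sym == "":
                continue  # terminal gap run: row does not cover this position
            n_eff += 1
            if sym == "-":
                n_indel += 1
            else:
                counts[sym] = counts.get(sym, 0) + 1
        ref = min(counts, key=lambda b: (-counts[b], _BASE_ORDER.get(b, 9)))
        n_res = sum(counts.values())
        consensus.append(ref)
        subst.append((n_res - counts[ref]) / n_eff)
        indel.append(n_indel / n_eff)
        eff.append(n_eff)
    return DivergenceProfile(
        strand_label,
        kept,
        consensus,
        np.array(subst),
        np.array(indel),
        np.array(eff, dtype=int),
    )


def region_summary(
    profile: DivergenceProfile, region: RegionSpec
) -> tuple[float, float, float]:
    """(mean_subst, max_subst, mean_indel) over a strand-local region."""
    idx = [p - 1 for p in region.positions if 1 <= p <= profile.length]
    dropped = [p for p in region.positions if p > profile.length or p < 1]
    if dropped:
        warnings.warn(
            f"{profile.strand_label}/{region.name}: positions {dropped} beyond "
            f"profile length {profile.length} dropped",
            stacklevel=2,
        )
    if not idx:
        raise RegionError(
            f"region {region.name!r} disjoint from profile of length {profile.length}"
        )
    return (
        float(np.mean(profile.subst_fraction[idx])),
        float(np.max(profile.subst_fraction[idx])),
        float(np.mean(profile.indel_fraction[idx])),
    )


def classify_strand(
    profile: DivergenceProfile,
    theta_pos: float = 0.1,
    theta_mean: float = 0.15,
    seed: RegionSpec = SEED,
    anchor: RegionSpec = ANCHOR,
) -> ConservationCall:
    """Call a strand mature-like-conserved or diverged.

    A strand is mature-like-conserved when no seed position exceeds
    ``theta_pos`` (inclusive) and the overall mean substitution fraction is at
    most ``theta_mean``; both thresholds are echoed in the call.
    """
    _, seed_max, _ = region_summary(profile, seed)
    seed_conserved = seed_max <= theta_pos
    try:
        _, anchor_max, _ = region_summary(profile, anchor)
        anchor_conserved = anchor_max <= theta_pos
    except RegionError:
        anchor_conserved = False
    mean_subst = profile.mean_subst
    category = (
        "mature-like-conserved"
        if (seed_conserved and mean_subst <= theta_mean)
        else "diverged"
    )
    return ConservationCall(
        profile.strand_label,
        seed_conserved,
        anchor_conserved,
        mean_subst,
        category,
        (theta_pos, theta_mean),
    )


@dataclass(frozen=True)
class StrandComparison:
    means: dict[str, float]
    ordering: str  # e.g. "mature < star < loop", "=" marks ties


def compare_strand_regions(
    mature_profile: DivergenceProfile,
    star_profile: DivergenceProfile,
    loop_profile: DivergenceProfile,
) -> StrandComparison:
    """Descriptive ordering of mean substitution across the three strands."""
    means = {
        mature_profile.strand_label: mature_profile.mean_subst,
        star_profile.strand_label: star_profile.mean_subst,
        loop_profile.strand_label: loop_profile.mean_subst,
    }
    ranked = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    parts = [ranked[0][0]]
    for (prev_l, prev_v), (lab, val) in zip(ranked, ranked[1:]):
        parts.append("=" if val == prev_v else "<")
        parts.append(lab)
    return StrandComparison(means, " ".join(parts))
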