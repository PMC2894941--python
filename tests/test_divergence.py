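"""Per-position substitution profiles, region summaries, conservation calls."""

import numpy as np
import pytest

from mirstar import errors
from mirstar.divergence import (
    ANCHOR,
    SEED,
    DivergenceProfile,
    classify_strand,
    compare_strand_regions,
    region_summary,
    strand_profile,
)
from mirstar.family_msa import Alignment

from conftest import random_rna
from oracles import naive_profile


def _full_projections(aln):
    out = {}
    for rid, row in zip(aln.row_ids, aln.rows):
        out[rid] = [c + 1 for c, ch in enumerate(row) if ch != "-"]
    return out


def test_profile_simple_substitution():
    aln = Alignment(["a", "b", "c"], ["AUGC", "AUGC", "AUGU"])
    prof = strand_profile(aln, _full_projections(aln))
    assert prof.length == 4
    assert prof.consensus == ["A", "U", "G", "C"]
    assert prof.subst_fraction[3] == pytest.approx(1 / 3)
    assert prof.subst_fraction[:3] == pytest.approx([0, 0, 0])
    assert np.all(prof.indel_fraction == 0)


def test_profile_terminal_gap_exclusion():
    aln = Alignment(["a", "b"], ["--GC", "AUGC"])
    prof = strand_profile(aln, _full_projections(aln))
    # row a does not cover positions 1-2: effective_n 1, no substitutions
    assert list(prof.effective_n) == [1, 1, 2, 2]
    assert np.all(prof.subst_fraction == 0)


def test_profile_internal_gap_counts_as_indel():
    aln = Alignment(["a", "b"], ["A-GC", "AUGC"])
    prof = strand_profile(aln, _full_projections(aln))
    assert prof.indel_fraction[1] == pytest.approx(0.5)
    assert prof.subst_fraction[1] == 0.0


def test_profile_consensus_tie_breaks_lexicographically():
    aln = Alignment(["a", "b"], ["G", "A"])
    prof = strand_profile(aln, _full_projections(aln))
    assert prof.consensus == ["A"]
    assert prof.subst_fraction[0] == pytest.approx(0.5)


def _random_case(rng):
    nrows = int(rng.integers(2, 8))
    ncol = int(rng.integers(6, 30))
    rows = []
    for _ in range(nrows):
        row = list(random_rna(rng, ncol))
        for c in range(ncol):
            if rng.random() < 0.15:
                row[c] = "-"
        rows.append("".join(row))
    # ensure no all-gap column
    rows = [
        "".join(
            (r[c] if any(x[c] != "-" for x in rows) else "A") for c in range(ncol)
        )
        for r in rows
    ]
    aln = Alignment([f"r{k}" for k in range(nrows)], rows)
    proj = {}
    for rid, row in zip(aln.row_ids, aln.rows):
        residues = [c + 1 for c, ch in enumerate(row) if ch != "-"]
        if len(residues) < 2:
            return None
        lo = int(rng.integers(0, max(1, len(residues) // 3)))
        hi = int(rng.integers(2 * len(residues) // 3, len(residues)))
        span = (lo + 1, hi + 1 if hi >= lo + 1 else lo + 2)
        cols = residues[span[0] - 1 : span[1]]
        proj[rid] = cols
    return aln, proj


def test_profile_matches_naive_recount(rng):
    checked = 0
    while checked < 50:
        case = _random_case(rng)
        if case is None:
            continue
        aln, proj = case
        rows = dict(zip(aln.row_ids, aln.rows))
        kept, consensus, subst, indel, eff = naive_profile(rows, proj)
        try:
            prof = strand_profile(aln, proj)
        except errors.EmptyProfileError:
            assert not kept
            checked += 1
            continue
        assert prof.columns == kept
        assert prof.consensus == consensus
        assert prof.subst_fraction == pytest.approx(subst)
        assert prof.indel_fraction == pytest.approx(indel)
        assert list(prof.effective_n) == eff
        checked += 1


def test_profile_permutation_invariant(rng):
    case = None
    while case is None:
        case = _random_case(rng)
    aln, proj = case
    prof = strand_profile(aln, proj)
    order = list(proj)[::-1]
    prof2 = strand_profile(aln, {k: proj[k] for k in order})
    assert prof.consensus == prof2.consensus
    assert prof.subst_fraction == pytest.approx(prof2.subst_fraction)


def test_duplicate_row_never_increases_substitution(rng):
    aln = Alignment(["a", "b", "c"], ["AUGC", "AAGC", "AUGU"])
    proj = _full_projections(aln)
    prof = strand_profile(aln, proj)
    aln2 = Alignment(["a", "b", "c", "a2"], ["AUGC", "AAGC", "AUGU", "AUGC"])
    proj2 = _full_projections(aln2)
    prof2 = strand_profile(aln2, proj2)
    assert np.all(prof2.subst_fraction <= prof.subst_fraction + 1e-12)


def _profile_from(subst, label="strand"):
    n = len(subst)
    return DivergenceProfile(
        label, list(range(1, n + 1)), ["A"] * n, np.array(subst, float),
        np.zeros(n), np.full(n, 4),
    )


def test_region_summary_cases():
    prof = _profile_from([0.0] * 22)
    assert region_summary(prof, SEED) == (0.0, 0.0, 0.0)
    prof2 = _profile_from([0, 0.1] + [0] * 20)
    mean, mx, _ = region_summary(prof2, SEED)
    assert mean == pytest.approx(0.1 / 7)
    assert mx == pytest.approx(0.1)
    from mirstar.divergence import RegionSpec

    with pytest.warns(UserWarning, match="dropped"):
        with pytest.raises(errors.RegionError):
            region_summary(prof, RegionSpec("custom", (30,)))


def test_region_summary_warns_on_out_of_range_positions():
    prof = _profile_from([0.0] * 14)  # anchor positions 15-16 fall off the end
    with pytest.warns(UserWarning, match="dropped"):
        mean, mx, _ = region_summary(prof, ANCHOR)
    assert mean == 0.0 and mx == 0.0


def test_classify_all_zero_is_conserved():
    call = classify_strand(_profile_from([0.0] * 22))
    assert call.category == "mature-like-conserved"
    assert call.seed_conserved and call.anchor_conserved


def test_classify_seed_substitution_forces_diverged():
    subst = [0.0] * 22
    subst[3] = 0.4  # position 4 is in the seed
    call = classify_strand(_profile_from(subst))
    assert not call.seed_conserved
    assert call.category == "diverged"


def test_classify_threshold_boundaries_inclusive():
    subst = [0.0] * 22
    for k in range(8, 19):  # outside the seed; mean lands exactly on theta_mean
        subst[k] = 0.3
    call = classify_strand(_profile_from(subst))
    assert call.mean_subst == pytest.approx(0.15)
    assert call.seed_conserved
    assert call.category == "mature-like-conserved"


def test_compare_strand_regions_ordering():
    cmp = compare_strand_regions(
        _profile_from([0.02] * 22, "mature"),
        _profile_from([0.10] * 22, "star"),
        _profile_from([0.40] * 10, "loop"),
    )
    assert cmp.ordering == "mature < star < loop"
    tie = compare_strand_regions(
        _profile_from([0.1] * 4, "mature"),
        _profile_from([0.1] * 4, "star"),
        _profile_from([0.4] * 4, "loop"),
    )
    assert tie.ordering == "mature = star < loop"
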