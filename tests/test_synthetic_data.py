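"""Ground-truth simulator: determinism, layout, rate calibration, presets."""

import json

import numpy as np
import pytest

from mirstar.hairpin_structure import fold_nussinov, infer_star_duplex
from mirstar.mirbase_io import parse_name
from mirstar.synthetic_data import (
    SimParams,
    build_ancestor,
    evolve,
    make_family,
    make_fixture,
    simulate_preset,
    with_stem_bulges,
)


def test_simparams_validation():
    with pytest.raises(ValueError):
        SimParams(seed_rate=-0.1)
    with pytest.raises(ValueError):
        SimParams(star_mode="bogus")
    assert SimParams(star_mode="conserved").resolved_star_rate() == SimParams().mature_other_rate
    assert SimParams(star_mode="diverged").resolved_star_rate() == SimParams().loop_rate


def test_ancestor_region_spans_partition_hairpin(rng):
    anc = build_ancestor(SimParams(), rng)
    covered = []
    for name in ("flank5", "mature", "loop", "star", "flank3"):
        s, e = anc.spans[name]
        covered.extend(range(s, e + 1))
    assert covered == list(range(1, len(anc.sequence) + 1))
    assert anc.mature_span[1] - anc.mature_span[0] + 1 == 22
    # strand-local seed/anchor tags sit at mature positions 2-8 and 13-16
    m_s = anc.mature_span[0]
    for k in range(1, 23):
        tag = anc.tags[m_s + k - 2]
        if 2 <= k <= 8:
            assert tag == "seed"
        elif 13 <= k <= 16:
            assert tag == "anchor"
        else:
            assert tag == "mature_other"


def test_ancestor_star_recovered_by_duplex_rule(rng):
    anc = build_ancestor(SimParams(), rng)
    pm = fold_nussinov(anc.sequence)
    assert infer_star_duplex("anc", pm, anc.mature_span).span == anc.star_span


def test_bulged_stem_fixture_keeps_mature_span(rng):
    anc = build_ancestor(SimParams(), rng)
    seq, mature_span, true_star = with_stem_bulges(anc, 1, rng)
    assert mature_span == anc.mature_span
    assert true_star == (anc.star_span[0], anc.star_span[1] + 1)
    assert len(seq) == len(anc.sequence) + 1


def test_zero_rates_reproduce_ancestor(rng):
    params = SimParams(
        seed_rate=0, anchor_rate=0, mature_other_rate=0, star_rate=0,
        loop_rate=0, flank_rate=0, loop_indel_rate=0, star_mode="conserved",
    )
    anc = build_ancestor(params, rng)
    leaves = evolve(anc, params.tree, params, rng, star_rate=0.0)
    assert len(leaves) == 8
    assert all(leaf.sequence == anc.sequence for leaf in leaves)


def test_zero_length_branches_reproduce_ancestor(rng):
    params = SimParams(tree="(A:0,B:0);")
    anc = build_ancestor(params, rng)
    leaves = evolve(anc, params.tree, params, rng)
    assert all(leaf.sequence == anc.sequence for leaf in leaves)


def test_same_seed_is_byte_identical(tmp_path):
    a = make_fixture("mir124_like", tmp_path / "a", rng_seed=7)
    b = make_fixture("mir124_like", tmp_path / "b", rng_seed=7)
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes()


def test_two_taxon_p_distance_matches_jc_expectation(rng):
    r, tau = 0.1, 1.0
    params = SimParams(
        seed_rate=r, anchor_rate=r, mature_other_rate=r, star_rate=r,
        loop_rate=r, flank_rate=r, loop_indel_rate=0.0,
        tree="(A:0.5,B:0.5);", star_mode="conserved",
    )
    diffs = total = 0
    for _ in range(50):
        anc = build_ancestor(params, rng)
        a, b = evolve(anc, params.tree, params, rng, star_rate=r)
        diffs += sum(x != y for x, y in zip(a.sequence, b.sequence))
        total += len(anc.sequence)
    expected = 0.75 * (1 - np.exp(-4 * r * tau / 3))
    assert expected == pytest.approx(0.0936, abs=5e-4)
    se = np.sqrt(expected * (1 - expected) / total)
    assert abs(diffs / total - expected) <= 3 * se


def test_duplication_forks_paralogs(rng):
    params = SimParams(duplication_prob=1.0)
    fam = make_family(params, rng, family_name="mir-77")
    ids = [h.id for h in fam.hairpins]
    assert len(ids) > 8  # every internal edge forked a copy
    copies = [i for i in ids if parse_name(i).copy is not None]
    assert copies, "multicopy precursors should carry copy suffixes"
    assert len(set(ids)) == len(ids)
    assert any(l["is_paralog"] for l in fam.truth["leaves"])


def test_let7_preset_structure():
    (fam,) = simulate_preset("let7_like")
    ids = [h.id for h in fam.hairpins]
    assert len(ids) == 12
    assert {"hsa-let-7a-1", "hsa-let-7a-2", "hsa-let-7a-3"} <= set(ids)
    assert all(parse_name(i).stem == "let-7" for i in ids)
    matures = {m.hairpin_id: m.sequence for m in fam.matures if m.role == "mature"}
    trio = {matures[f"hsa-let-7a-{k}"] for k in (1, 2, 3)}
    assert len(trio) == 1, "multicopy precursors share one identical mature"
    stars = [m.sequence for m in fam.matures if m.role == "star"]
    assert len(set(stars)) > 1, "star strands diverge across copies"


def test_mixed_star_cohort_balanced_labels():
    families = simulate_preset("mixed_star_cohort")
    assert len(families) == 50
    labels = [f.star_class for f in families]
    assert labels.count("conserved") == 25
    assert labels.count("diverged") == 25
    keys = [f.family_key for f in families]
    assert len(set(keys)) == 50


def test_fixture_bundle_files(tmp_path):
    paths = make_fixture("let7_like", tmp_path)
    truth = json.loads(paths["truth"].read_text())
    assert truth["preset"] == "let7_like"
    fam = truth["families"][0]
    assert len(fam["leaves"]) == 12
    from mirstar.mirbase_io import load_hairpins, load_matures

    hairpins = load_hairpins(paths["hairpins"])
    matures = load_matures(paths["matures"])
    assert len(hairpins) == 12 and len(matures) == 24
    spans = {l["hairpin_id"]: l for l in fam["leaves"]}
    for hp in hairpins:
        s, e = spans[hp.id]["mature_span"]
        assert 1 <= s <= e <= len(hp.sequence)
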