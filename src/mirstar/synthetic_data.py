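"""Simulated miRNA gene families with known ground truth.

The generator builds an ancestral hairpin with an explicit region layout -
5' flank, 22-nt mature on the 5' arm (seed positions 2-8, anchor 13-16
strand-local), terminal loop, 22-nt star, 3' flank - where the star is the
reverse complement of the mature duplex region arranged so both duplex ends
carry 2-nt 3' overhangs.  The hairpin then evolves down a species tree under
Jukes-Cantor substitution with region-specific rates (per branch of length t
a site in region R substitutes with probability 3/4*(1 - exp(-4*r_R*t/3))),
single-base loop indels as a Poisson process, and optional whole-hairpin
duplications that fork paralog lineages whose star and loop evolve faster.

Because substitution is site-independent JC - the same model the analysis
assumes - the simulator tests self-consistency of the pipeline, not realism:
no covarion behaviour, no structure-constrained compensatory changes, no
expression or arm-switching dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from . import mirbase_io
from .hairpin_structure import fold_nussinov, infer_star_duplex
from .mirbase_io import HairpinRecord, MatureRecord

BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}

MATURE_LEN = 22
DUPLEX_PAIRS = MATURE_LEN - 2  # both duplex ends carry 2-nt 3' overhangs

#: 8 vertebrate species, balanced ultrametric tree of height (depth) 1
DEFAULT_TREE = (
    "(((hsa:0.3334,mmu:0.3334):0.3333,(gga:0.3334,xtr:0.3334):0.3333):0.3333,"
    "((dre:0.3334,fru:0.3334):0.3333,(tni:0.3334,mdo:0.3334):0.3333):0.3333);"
)

REGION_TAGS = ("flank5", "seed", "anchor", "mature_other", "loop", "star", "flank3")


@dataclass(frozen=True)
class SimParams:
    """Region-specific substitution rates (subst/site/unit time) and layout.

    ``star_mode`` ties the star rate to the mature body (``conserved``), to
    the loop (``diverged``), or alternates family by family (``mixed``).
    """

    seed_rate: float = 0.01
    anchor_rate: float = 0.02
    mature_other_rate: float = 0.05
    star_rate: float = 0.05
    loop_rate: float = 0.5
    flank_rate: float = 0.3
    tree: str = DEFAULT_TREE
    n_families: int = 1
    duplication_prob: float = 0.0
    loop_indel_rate: float = 0.05
    star_mode: str = "conserved"
    paralog_rate_boost: float = 1.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "seed_rate",
            "anchor_rate",
            "mature_other_rate",
            "star_rate",
            "loop_rate",
            "flank_rate",
            "loop_indel_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.duplication_prob <= 1:
            raise ValueError("duplication_prob must lie in [0, 1]")
        if self.star_mode not in ("conserved", "diverged", "mixed"):
            raise ValueError(f"unknown star_mode {self.star_mode!r}")

    def resolved_star_rate(self, family_index: int = 0) -> float:
        if self.star_mode == "conserved":
            return self.mature_other_rate
        if self.star_mode == "diverged":
            return self.loop_rate
        return self.mature_other_rate if family_index % 2 == 0 else self.loop_rate

    def rates(self, star_rate: float) -> dict[str, float]:
        return {
            "flank5": self.flank_rate,
            "seed": self.seed_rate,
            "anchor": self.anchor_rate,
            "mature_other": self.mature_other_rate,
            "loop": self.loop_rate,
            "star": star_rate,
            "flank3": self.flank_rate,
        }


@dataclass
class Ancestor:
    sequence: str
    tags: tuple[str, ...]  # one REGION_TAGS entry per position
    spans: dict[str, tuple[int, int]]  # 1-based inclusive, incl. mature/star/loop

    @property
    def mature_span(self) -> tuple[int, int]:
        return self.spans["mature"]

    @property
    def star_span(self) -> tuple[int, int]:
        return self.spans["star"]


def _mature_tags() -> list[str]:
    tags = []
    for k in range(1, MATURE_LEN + 1):
        if 2 <= k <= 8:
            tags.append("seed")
        elif 13 <= k <= 16:
            tags.append("anchor")
        else:
            tags.append("mature_other")
    return tags


def build_ancestor(params: SimParams, rng: np.random.Generator) -> Ancestor:
    """Build an ancestral hairpin whose fold recovers the star span exactly.

    The mature duplex body is drawn over {A,C,G} with A-rich flanks/loop and
    a C-rich 3' flank so that the intended stem is the unique maximum
    pairing; the construction is verified against :func:`fold_nussinov` and
    the duplex rule, resampling the mature on the rare failure.
    """
    f5 = int(rng.integers(5, 16))
    loop_len = int(rng.integers(8, 21))
    f3 = int(rng.integers(5, 16))
    for _ in range(50):
        # composition is constrained so no pairing can compete with the
        # intended stem: mature body over {A,C,G} (no U), 5' flank and loop
        # over {A,C}, 3' flank all C (no partner for the star tail); any
        # alternative pair then crosses an intended one, and the fold is
        # verified below regardless
        mature_body = "".join(rng.choice(["A", "C", "G"], size=DUPLEX_PAIRS))
        mature = mature_body + "AA"
        star = mature_body[::-1].translate(str.maketrans(_COMP)) + "AA"
        flank5 = "".join(rng.choice(["A", "C"], size=f5))
        loop = "".join(rng.choice(["A", "C"], size=loop_len))
        seq = flank5 + mature + loop + star + "C" * f3
        tags = (
            ["flank5"] * f5
            + _mature_tags()
            + ["loop"] * loop_len
            + ["star"] * MATURE_LEN
            + ["flank3"] * f3
        )
        m_s, m_e = f5 + 1, f5 + MATURE_LEN
        s_s = f5 + MATURE_LEN + loop_len + 1
        s_e = s_s + MATURE_LEN - 1
        pm = fold_nussinov(seq)
        try:
            call = infer_star_duplex("ancestor", pm, (m_s, m_e))
        except Exception:
            continue
        paired = sum(1 for p in range(m_s, m_e + 1) if pm.partner(p) is not None)
        if call.span == (s_s, s_e) and paired >= 0.9 * MATURE_LEN:
            spans = {
                "flank5": (1, f5),
                "mature": (m_s, m_e),
                "loop": (m_e + 1, s_s - 1),
                "star": (s_s, s_e),
                "flank3": (s_e + 1, s_e + f3),
            }
            return Ancestor(seq, tuple(tags), spans)
    raise RuntimeError("could not build a verifiable ancestor")  # pragma: no cover


def with_stem_bulges(
    ancestor: Ancestor, n_bulges: int, rng: np.random.Generator, max_tries: int = 30
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Insert 1-2 single-base interior bulges into the star arm of a stem.

    Returns ``(sequence, mature_span, true_star_span)`` for a hairpin whose
    fold still shows the (now interrupted) duplex stem; insertion positions
    are resampled if base-pair maximization rearranges the structure
    instead, since the point of these fixtures is endpoint tolerance of the
    duplex rule, not fold stability on arbitrary sequences.
    """
    s_s, s_e = ancestor.star_span
    m_s, m_e = ancestor.mature_span
    for _ in range(max_tries):
        offs = sorted(
            (int(o) for o in rng.integers(s_s + 4, s_e - 6, size=n_bulges)), reverse=True
        )
        seq = ancestor.sequence
        for off in offs:
            seq = seq[: off - 1] + "A" + seq[off - 1 :]
        true_span = (s_s, s_e + n_bulges)
        pm = fold_nussinov(seq)
        partners = [pm.partner(p) for p in range(m_s, m_e + 1) if pm.partner(p) is not None]
        if len(partners) >= DUPLEX_PAIRS - 2 and all(
            true_span[0] - 2 <= q <= true_span[1] + 2 for q in partners
        ):
            return seq, (m_s, m_e), true_span
    raise RuntimeError("no bulge placement kept the stem intact")


@dataclass
class SimLeaf:
    label: str  # species / gene-tree leaf label
    sequence: str
    tags: tuple[str, ...]
    is_paralog: bool = False


def _substitute(seq: list[str], tags: list[str], t: float, rates: dict[str, float],
                rng: np.random.Generator) -> None:
    if t <= 0:
        return
    probs = np.array([0.75 * -np.expm1(-4.0 * rates[tag] * t / 3.0) for tag in tags])
    hits = np.nonzero(rng.random(len(seq)) < probs)[0]
    for idx in hits:
        alternatives = [b for b in "ACGU" if b != seq[idx]]
        seq[idx] = alternatives[int(rng.integers(3))]


def _loop_indels(seq: list[str], tags: list[str], t: float, indel_rate: float,
                 rng: np.random.Generator) -> None:
    if t <= 0 or indel_rate <= 0:
        return
    loop_idx = [i for i, tg in enumerate(tags) if tg == "loop"]
    n_events = int(rng.poisson(indel_rate * t * len(loop_idx)))
    for _ in range(n_events):
        loop_idx = [i for i, tg in enumerate(tags) if tg == "loop"]
        if not loop_idx:
            break
        if rng.random() < 0.5 and len(loop_idx) > 4:  # deletion, keep loop viable
            k = loop_idx[int(rng.integers(len(loop_idx)))]
            del seq[k]
            del tags[k]
        else:  # insertion
            k = loop_idx[int(rng.integers(len(loop_idx)))]
            seq.insert(k, str(BASES[int(rng.integers(4))]))
            tags.insert(k, "loop")


def evolve(
    ancestor: Ancestor,
    tree: str,
    params: SimParams,
    rng: np.random.Generator,
    star_rate: float | None = None,
) -> list[SimLeaf]:
    """Evolve the ancestor down a Newick tree; returns one leaf per lineage.

    With ``duplication_prob`` > 0, an edge into an internal node may fork an
    independently re-evolved paralog of the whole hairpin; paralog star and
    loop rates are multiplied by ``paralog_rate_boost``.
    """
    if star_rate is None:
        star_rate = params.resolved_star_rate()
    base_rates = params.rates(star_rate)
    boosted = dict(base_rates)
    boosted["star"] *= params.paralog_rate_boost
    boosted["loop"] *= params.paralog_rate_boost
    t = dendropy.Tree.get(data=tree, schema="newick")
    if len(t.leaf_nodes()) < 2:
        raise ValueError("tree needs at least 2 leaves")
    leaves: list[SimLeaf] = []

    def branch(state, length, is_paralog):
        seq, tags = list(state[0]), list(state[1])
        rates = boosted if is_paralog else base_rates
        _substitute(seq, tags, length, rates, rng)
        _loop_indels(seq, tags, length, params.loop_indel_rate, rng)
        return seq, tags

    def walk(node, state, is_paralog):
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            child_state = branch(state, length, is_paralog)
            if child.is_leaf():
                leaves.append(
                    SimLeaf(
                        child.taxon.label,
                        "".join(child_state[0]),
                        tuple(child_state[1]),
                        is_paralog,
                    )
                )
            else:
                walk(child, child_state, is_paralog)
                if rng.random() < params.duplication_prob:
                    dup_state = branch(state, length, True)
                    walk(child, dup_state, True)

    walk(t.seed_node, (list(ancestor.sequence), list(ancestor.tags)), False)
    return leaves


def _leaf_spans(tags: Sequence[str]) -> dict[str, tuple[int, int]]:
    spans = {}
    mature_tags = {"seed", "anchor", "mature_other"}
    pos_by_kind: dict[str, list[int]] = {"mature": [], "star": [], "loop": []}
    for i, tg in enumerate(tags, start=1):
        if tg in mature_tags:
            pos_by_kind["mature"].append(i)
        elif tg in ("star", "loop"):
            pos_by_kind[tg].append(i)
    for kind, positions in pos_by_kind.items():
        if positions:
            spans[kind] = (positions[0], positions[-1])
    return spans


@dataclass
class SimFamily:
    family_key: str
    star_class: str  # conserved | diverged
    ancestor: Ancestor
    hairpins: list[HairpinRecord]
    matures: list[MatureRecord]
    truth: dict


def make_family(
    params: SimParams,
    rng: np.random.Generator,
    family_name: str = "mir-900",
    family_index: int = 0,
    name_prefix: str | None = None,
    label_map: dict[str, str] | None = None,
    star_rate: float | None = None,
) -> SimFamily:
    """Simulate one gene family and package it as miRBase-dialect records.

    By default leaves are named ``<species>-<family>[-copy]``; with
    ``name_prefix`` set, (optionally remapped) leaf labels are appended to
    the prefix instead (single-species gene trees such as the let-7 preset).
    """
    if star_rate is None:
        star_rate = params.resolved_star_rate(family_index)
    star_class = "conserved" if star_rate <= params.mature_other_rate else "diverged"
    ancestor = build_ancestor(params, rng)
    leaves = evolve(ancestor, params.tree, params, rng, star_rate=star_rate)

    hairpins: list[HairpinRecord] = []
    matures: list[MatureRecord] = []
    counts: dict[str, int] = {}
    for leaf in leaves:
        counts[leaf.label] = counts.get(leaf.label, 0) + 1
    seen: dict[str, int] = {}
    truth_leaves = []
    for leaf in leaves:
        seen[leaf.label] = seen.get(leaf.label, 0) + 1
        if name_prefix is not None:
            label = label_map.get(leaf.label, leaf.label) if label_map else leaf.label
            hid = f"{name_prefix}{label}"
            if counts[leaf.label] > 1:
                hid += f"-{seen[leaf.label]}"
        else:
            hid = f"{leaf.label}-{family_name}"
            if counts[leaf.label] > 1:
                hid += f"-{seen[leaf.label]}"
        spans = _leaf_spans(leaf.tags)
        hairpins.append(HairpinRecord.from_fasta(hid, leaf.sequence))
        mat_id = hid.replace("mir", "miR").replace("let", "let")
        m_span, s_span = spans["mature"], spans["star"]
        matures.append(
            MatureRecord(
                mat_id,
                leaf.sequence[m_span[0] - 1 : m_span[1]],
                hairpin_id=hid,
                role="mature",
                arm="5p",
                span=m_span,
            )
        )
        matures.append(
            MatureRecord(
                mat_id + "*",
                leaf.sequence[s_span[0] - 1 : s_span[1]],
                hairpin_id=hid,
                role="star",
                arm="3p",
                span=s_span,
            )
        )
        truth_leaves.append(
            {
                "hairpin_id": hid,
                "is_paralog": leaf.is_paralog,
                "mature_span": list(m_span),
                "star_span": list(s_span),
                "loop_span": list(spans["loop"]),
            }
        )
    truth = {
        "family_key": family_name,
        "star_class": star_class,
        "rates": params.rates(star_rate),
        "loop_indel_rate": params.loop_indel_rate,
        "tree": params.tree,
        "ancestor_sequence": ancestor.sequence,
        "ancestor_spans": {k: list(v) for k, v in ancestor.spans.items()},
        "leaves": truth_leaves,
    }
    return SimFamily(family_name, star_class, ancestor, hairpins, matures, truth)


# ---------------------------------------------------------------------------
# presets

#: 12-member single-species let-7-like gene tree; the a-1/a-2/a-3 copies form
#: one shallow clade, mirroring a multicopy precursor trio.
LET7_TREE = (
    "((((a1:0.15,a2:0.15):0.1,a3:0.25):0.35,((b:0.3,c:0.3):0.2,d:0.5):0.1):0.4,"
    "(((e:0.25,(f1:0.1,f2:0.1):0.15):0.25,g:0.5):0.3,(i:0.4,j:0.4):0.4):0.2);"
)
_LET7_VARIANTS = {
    "a1": "a-1", "a2": "a-2", "a3": "a-3", "b": "b", "c": "c", "d": "d",
    "e": "e", "f1": "f-1", "f2": "f-2", "g": "g", "i": "i", "j": "j",
}

PRESET_SEEDS = {"let7_like": 701, "mir124_like": 124, "mixed_star_cohort": 507}


def _let7_like(rng: np.random.Generator) -> list[SimFamily]:
    # mature region rates 0 guarantee identical matures across all copies
    params = SimParams(
        seed_rate=0.0,
        anchor_rate=0.0,
        mature_other_rate=0.0,
        star_rate=0.25,
        loop_rate=0.6,
        flank_rate=0.3,
        tree=LET7_TREE,
        loop_indel_rate=0.03,
        star_mode="diverged",
    )
    fam = make_family(
        params,
        rng,
        family_name="let-7",
        name_prefix="hsa-let-7",
        label_map=_LET7_VARIANTS,
        star_rate=0.25,
    )
    return [fam]


def _mir124_like(rng: np.random.Generator) -> list[SimFamily]:
    params = SimParams(
        seed_rate=0.005,
        anchor_rate=0.01,
        mature_other_rate=0.02,
        star_rate=0.02,
        loop_rate=0.3,
        flank_rate=0.2,
        loop_indel_rate=0.01,
        star_mode="conserved",
    )
    return [make_family(params, rng, family_name="mir-124")]


def _mixed_star_cohort(rng: np.random.Generator) -> list[SimFamily]:
    families = []
    for k in range(50):
        star_mode = "conserved" if k < 25 else "diverged"
        params = SimParams(
            seed_rate=0.01,
            anchor_rate=0.02,
            mature_other_rate=0.05,
            star_rate=0.05 if star_mode == "conserved" else 0.5,
            loop_rate=0.5,
            flank_rate=0.3,
            loop_indel_rate=0.05,
            star_mode=star_mode,
        )
        families.append(make_family(params, rng, family_name=f"mir-{800 + k}", family_index=k))
    return families


_PRESETS = {
    "let7_like": _let7_like,
    "mir124_like": _mir124_like,
    "mixed_star_cohort": _mixed_star_cohort,
}


def simulate_preset(preset: str, rng_seed: int | None = None) -> list[SimFamily]:
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    seed = PRESET_SEEDS[preset] if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    return _PRESETS[preset](rng)


def make_fixture(preset: str, outdir: str | Path, rng_seed: int | None = None) -> dict[str, Path]:
    """Write a preset bundle: hairpin FASTA, mature FASTA, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = simulate_preset(preset, rng_seed)
    hp_path = outdir / "hairpins.fasta"
    mat_path = outdir / "matures.fasta"
    truth_path = outdir / "truth.json"
    mirbase_io.write_fasta([h for f in families for h in f.hairpins], hp_path)
    mirbase_io.write_fasta([m for f in families for m in f.matures], mat_path)
    truth = {
        "preset": preset,
        "rng_seed": PRESET_SEEDS[preset] if rng_seed is None else rng_seed,
        "families": [f.truth for f in families],
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"hairpins": hp_path, "matures": mat_path, "truth": truth_path}
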