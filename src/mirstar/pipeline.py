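"""End-to-end orchestration: records -> families -> strand profiles -> calls
-> split networks, with deterministic byte-stable outputs.

Per family the pipeline maps matures onto hairpins, obtains a star span for
every member (reported record, homology transfer from a member with a
reported star, or the structural duplex rule as last resort), aligns the
precursors, projects the mature/star/loop spans into alignment columns,
profiles each strand, classifies conservation, and builds a neighbor-net
split network from Jukes-Cantor distances.  Per-family failures are logged
and skipped rather than aborting the run, since real miRBase-dialect data
contain unmappable matures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import mirbase_io, synthetic_data
from .divergence import (
    ConservationCall,
    DivergenceProfile,
    classify_strand,
    compare_strand_regions,
    strand_profile,
)
from .errors import MirstarError
from .family_msa import AlignParams, Alignment, progressive_align, project_span
from .hairpin_structure import (
    StarCall,
    fold_nussinov,
    infer_star_duplex,
    infer_star_transfer,
    loop_span,
)
from .mirbase_io import HairpinRecord, MatureRecord, group_families, map_mature_to_hairpin
from .phylonet import jc_matrix, neighbor_net, write_distances, write_nexus


@dataclass
class RunConfig:
    hairpin_fasta: str | None = None
    mature_fasta: str | None = None
    preset: str | None = None
    dedupe: bool = False
    theta_pos: float = 0.1
    theta_mean: float = 0.15
    align_params: AlignParams = field(default_factory=AlignParams)
    outdir: str = "mirstar_out"
    rng_seed: int = 0

    def __post_init__(self):
        has_files = self.hairpin_fasta is not None
        if has_files == (self.preset is not None):
            raise ValueError("exactly one input source: FASTA files or a preset")
        if not (0 <= self.theta_pos <= 1 and 0 <= self.theta_mean <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class FamilyReport:
    family_key: str
    n_members: int
    n_species: int
    profiles: dict[str, DivergenceProfile]
    calls: dict[str, ConservationCall]
    star_methods: dict[str, str]
    ordering: str | None
    network_file: str | None


@dataclass
class RunResult:
    reports: list[FamilyReport]
    cohort: dict
    warnings: list[str]
    outdir: Path


def _match_hairpin(mature: MatureRecord, hairpins: Sequence[HairpinRecord]):
    """Find the precursor a mature/star record belongs to by name, else by
    unique sequence occurrence among same-species family members."""
    parts = mirbase_io.parse_name(mature.id)
    candidates = [
        h
        for h in hairpins
        if (h.species, h.stem, h.variant, h.copy)
        == (parts.species, parts.stem, parts.variant, parts.copy)
    ]
    if len(candidates) == 1:
        return candidates[0]
    pool = candidates or [
        h for h in hairpins if h.species == parts.species and h.stem == parts.stem
    ]
    hits = [h for h in pool if mature.sequence in h.sequence]
    return hits[0] if len(hits) == 1 else None


def _star_calls(
    members: list[HairpinRecord],
    mature_spans: dict[str, tuple[int, int]],
    reported_stars: dict[str, tuple[int, int]],
    params: AlignParams,
    warn: list[str],
) -> dict[str, StarCall]:
    calls: dict[str, StarCall] = {}
    ref_ids = sorted(reported_stars)
    by_id = {h.id: h for h in members}
    for hp in members:
        if hp.id in reported_stars:
            calls[hp.id] = StarCall(hp.id, reported_stars[hp.id], "reported", "")
            continue
        placed = False
        for rid in ref_ids:
            try:
                calls[hp.id] = infer_star_transfer(
                    hp.id, hp.sequence, by_id[rid].sequence, reported_stars[rid], params
                )
                placed = True
                break
            except MirstarError as exc:
                warn.append(f"transfer {rid}->{hp.id} failed: {exc}")
        if placed:
            continue
        if hp.id not in mature_spans:
            warn.append(f"{hp.id}: no mature span; star not called")
            continue
        try:
            pm = fold_nussinov(hp.sequence)
            calls[hp.id] = infer_star_duplex(hp.id, pm, mature_spans[hp.id])
        except MirstarError as exc:
            warn.append(f"{hp.id}: duplex star inference failed: {exc}")
    return calls


def _analyse_family(
    family_key: str,
    members: list[HairpinRecord],
    matures: list[MatureRecord],
    config: RunConfig,
    famdir: Path,
    warn: list[str],
) -> FamilyReport | None:
    if config.dedupe:
        seen: dict[str, str] = {}
        kept = []
        for h in members:
            if h.sequence in seen:
                warn.append(f"{family_key}: dropped {h.id} (duplicate of {seen[h.sequence]})")
            else:
                seen[h.sequence] = h.id
                kept.append(h)
        members = kept
    if len(members) < 2:
        warn.append(f"{family_key}: fewer than 2 members; skipped")
        return None

    mature_spans: dict[str, tuple[int, int]] = {}
    reported_stars: dict[str, tuple[int, int]] = {}
    for m in matures:
        if m.hairpin_id and m.span:
            if m.role == "star":
                reported_stars.setdefault(m.hairpin_id, m.span)
            else:
                mature_spans.setdefault(m.hairpin_id, m.span)
    members = [h for h in members if h.id in mature_spans or h.id in reported_stars]
    if len(members) < 2:
        warn.append(f"{family_key}: fewer than 2 members with mapped strands; skipped")
        return None

    star_calls = _star_calls(members, mature_spans, reported_stars, config.align_params, warn)
    loop_spans: dict[str, tuple[int, int]] = {}
    for hp in members:
        if hp.id in mature_spans and hp.id in star_calls:
            try:
                loop_spans[hp.id] = loop_span(mature_spans[hp.id], star_calls[hp.id].span)
            except MirstarError as exc:
                warn.append(f"{hp.id}: loop span failed: {exc}")

    aln = progressive_align([(h.id, h.sequence) for h in members], config.align_params)
    aln.write_fasta(famdir / "alignment.fasta")

    def projections(spans: dict[str, tuple[int, int]]):
        out = {}
        for rid, span in spans.items():
            if span[0] > span[1]:  # zero-length loop
                continue
            out[rid] = project_span(aln, rid, span)
        return out

    profiles: dict[str, DivergenceProfile] = {}
    calls: dict[str, ConservationCall] = {}
    for label, spans in (
        ("mature", mature_spans),
        ("star", {h: c.span for h, c in star_calls.items()}),
        ("loop", loop_spans),
    ):
        proj = projections({k: v for k, v in spans.items() if k in {h.id for h in members}})
        if len(proj) < 2:
            warn.append(f"{family_key}: <2 rows for {label} profile; skipped")
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                profiles[label] = strand_profile(aln, proj, strand_label=label)
                calls[label] = classify_strand(
                    profiles[label], config.theta_pos, config.theta_mean
                )
            except MirstarError as exc:
                warn.append(f"{family_key}/{label}: profiling failed: {exc}")
        warn.extend(f"{family_key}/{label}: {w.message}" for w in caught)

    ordering = None
    if {"mature", "star", "loop"} <= profiles.keys():
        ordering = compare_strand_regions(
            profiles["mature"], profiles["star"], profiles["loop"]
        ).ordering

    network_file = None
    try:
        D = jc_matrix(aln)
        warn.extend(f"{family_key}: {w}" for w in D.warnings)
        net = neighbor_net(D)
        write_distances(D, famdir / "distances.tsv")
        write_nexus(net, famdir / "network.nex")
        network_file = str(famdir / "network.nex")
    except MirstarError as exc:
        warn.append(f"{family_key}: network skipped: {exc}")

    if profiles:
        pd.concat([p.to_frame() for p in profiles.values()]).to_csv(
            famdir / "profiles.tsv", sep="\t", index=False, float_format="%.6f"
        )
    return FamilyReport(
        family_key,
        len(members),
        len({h.species for h in members}),
        profiles,
        calls,
        {h: c.method for h, c in star_calls.items()},
        ordering,
        network_file,
    )


def summarize_cohort(reports: Sequence[FamilyReport]) -> dict:
    """Cohort tallies: conserved-star fraction, seed co-conservation, means."""
    if not reports:
        raise ValueError("no family reports to summarize")
    star_calls = [r.calls["star"] for r in reports if "star" in r.calls]
    both_seed = [
        r.calls["mature"].seed_conserved and r.calls["star"].seed_conserved
        for r in reports
        if {"mature", "star"} <= r.calls.keys()
    ]

    def mean_of(label):
        vals = [r.profiles[label].mean_subst for r in reports if label in r.profiles]
        return float(np.mean(vals)) if vals else float("nan")

    return {
        "n_families": len(reports),
        "n_star_calls": len(star_calls),
        "star_conserved_fraction": (
            float(np.mean([c.category == "mature-like-conserved" for c in star_calls]))
            if star_calls
            else float("nan")
        ),
        "both_seeds_conserved_fraction": (
            float(np.mean(both_seed)) if both_seed else float("nan")
        ),
        "mean_mature_subst": mean_of("mature"),
        "mean_star_subst": mean_of("star"),
        "mean_loop_subst": mean_of("loop"),
    }


def run(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []

    if config.preset:
        paths = synthetic_data.make_fixture(config.preset, outdir / "sim", config.rng_seed or None)
        hairpins = mirbase_io.load_hairpins(paths["hairpins"])
        matures = mirbase_io.load_matures(paths["matures"])
    else:
        hairpins = mirbase_io.load_hairpins(config.hairpin_fasta)
        matures = (
            mirbase_io.load_matures(config.mature_fasta) if config.mature_fasta else []
        )

    by_id = {h.id: h for h in hairpins}
    mapped: list[MatureRecord] = []
    for m in matures:
        hp = _match_hairpin(m, hairpins)
        if hp is None:
            warn.append(f"{m.id}: no unique hairpin match; skipped")
            continue
        try:
            mapped.append(map_mature_to_hairpin(m, hp))
        except MirstarError as exc:
            warn.append(str(exc))
    families = group_families(hairpins)
    if not families:
        raise MirstarError("zero families after grouping")

    reports: list[FamilyReport] = []
    for fam in families:
        famdir = outdir / "families" / fam.family_key.replace("/", "_")
        famdir.mkdir(parents=True, exist_ok=True)
        members = [by_id[i] for i in fam.members]
        fam_matures = [m for m in mapped if m.hairpin_id in set(fam.members)]
        try:
            report = _analyse_family(fam.family_key, members, fam_matures, config, famdir, warn)
        except MirstarError as exc:
            warn.append(f"{fam.family_key}: failed: {exc}")
            report = None
        if report is not None:
            reports.append(report)

    calls_rows = []
    for r in reports:
        for label, call in sorted(r.calls.items()):
            calls_rows.append(
                {
                    "family_key": r.family_key,
                    "strand": label,
                    "seed_conserved": call.seed_conserved,
                    "anchor_conserved": call.anchor_conserved,
                    "mean_subst": f"{call.mean_subst:.6f}",
                    "category": call.category,
                    "theta_pos": call.thresholds_used[0],
                    "theta_mean": call.thresholds_used[1],
                }
            )
    pd.DataFrame(
        calls_rows,
        columns=[
            "family_key", "strand", "seed_conserved", "anchor_conserved",
            "mean_subst", "category", "theta_pos", "theta_mean",
        ],
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)

    cohort = summarize_cohort(reports) if reports else {}
    mirbase_io.write_annotation(mapped, outdir / "annotation.tsv")
    manifest = {
        "version": __version__,
        "config": {
            "hairpin_fasta": config.hairpin_fasta,
            "mature_fasta": config.mature_fasta,
            "preset": config.preset,
            "dedupe": config.dedupe,
            "theta_pos": config.theta_pos,
            "theta_mean": config.theta_mean,
            "align_params": asdict(config.align_params),
            "rng_seed": config.rng_seed,
        },
        "n_families_reported": len(reports),
        "cohort": {k: (round(v, 6) if isinstance(v, float) else v) for k, v in cohort.items()},
        "warnings": warn,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return RunResult(reports, cohort, warn, outdir)
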