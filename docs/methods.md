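# Methods

This note records the models, conventions and design choices behind
`mirstar`, and what the simulation-based tests do and do not establish.

## Coordinates, names and families

All sequence coordinates are 1-based inclusive on the hairpin precursor;
strand-local positions (seed = 2–8, anchor = 13–16) are 1-based on the
renumbered strand. Identifiers follow the miRBase dialect:
`<species>-<stem><variant>-<copy>` for precursors (`hsa-let-7a-1`),
`miR`-case with optional `-5p`/`-3p` or a trailing `*` for mature and star
strands. The species token is any 3-character code starting with a letter
(`hsa`, `sp1`); tokens that are themselves stem keywords (`mir`, `let`,
`lin`, …) are never consumed as species, and records without a recognizable
species are kept under `unk` rather than dropped. Gene families collapse
variant letters and copy numbers (`mir-125a`, `mir-125b-1` → `mir-125`),
matching how family-level analyses treat homologous genes; gene-level
outputs retain the full id.

## Hairpin structure and star-span inference

Folding is base-pair maximization (Nussinov dynamic programming) over
Watson–Crick plus G–U pairs with a minimum loop of 3 and deterministic
traceback (pairing preferred over bifurcation, smallest split point first).
This deliberately ignores stacking energies: for canonical miRNA stem-loops
the maximal nested pairing recovers the stem, and the module stays
dependency-free. It is *not* a thermodynamic predictor and will misfold
sequences with strong competing self-complementarity; the simulator
verifies each generated hairpin against the fold before using it.

Star spans are obtained three ways, recorded per call:

- **reported** — the star strand is present in the input and maps exactly;
- **transfer** — endpoints of a relative's known star are mapped through a
  pairwise global alignment, sliding inward past target gaps; transfers
  yielding spans under 15 nt fail (the pipeline then falls back to the
  duplex rule);
- **duplex** — from the fold: for a 5'-arm mature `(s, e)`,
  `star = (P'(e−2), P'(s)+2)`; for a 3'-arm mature,
  `star = (P'(e)−2, P'(s+2))`. `P'` extends the pairing map across interior
  bulges by scanning at most 3 nt to the nearest paired base and applying
  the antiparallel offset; beyond 3 nt the call errors rather than guessing.
  If fewer than half the mature positions are paired the structure is
  deemed too weak to place a duplex.

Transfer is attempted before the duplex rule because it most directly
mirrors predicting unknown stars from known relatives; the structural rule
is the fallback for families with no reported star at all.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh),
a gap of length k costing `gap_open + k·gap_extend`; defaults are
match 5, mismatch −4, gap_open 10, gap_extend 0.5 — standard nucleotide
settings, echoed in every run manifest since divergence numbers depend on
them. The multiple alignment is progressive: UPGMA guide tree from pairwise
p-distances (ties broken on lexicographic id pairs), then profile–profile
alignment with average sum-of-pairs column scores in which any comparison
against a gap scores 0. There is no sequence weighting and no
position-specific gap penalty; byte-identical agreement with external
aligners is not a goal, and alignment-dependent quantities are treated as
properties (orderings, conservation patterns), not exact values.

## The divergence statistic

For one strand across a family, each row's hairpin-local span is projected
into alignment columns. Strand positions are the ordered union of projected
columns retaining ≥50% residue occupancy, renumbered 1..L — this
operationalizes "positions 1 to ~22" when rows disagree slightly about
column usage. At each position:

- rows whose symbol falls in a terminal gap run of their own strand region
  are excluded (missing termini, e.g. ragged isomiR-like ends);
- the consensus is the most abundant residue among counted rows, ties
  broken A<C<G<U for determinism;
- `subst_fraction` is the share of counted rows differing from the
  consensus; internal gaps are reported separately as `indel_fraction`
  rather than folded into substitutions, so substitution-only and
  indel-aware readings are both available.

Repeated identical precursors are kept by default; `--dedupe` discards
them, the mode matching analyses that drop repeated family members. The
mode is logged because multicopy genes with identical matures otherwise
down-weight apparent divergence.

### Conservation thresholds and their granularity

A strand is *mature-like-conserved* iff max seed substitution ≤ θ_pos
(default 0.1) and mean substitution ≤ θ_mean (default 0.15), both
inclusive and both echoed in every output. The per-position rule is a
sharp instrument: with n counted rows the substitution fraction is
quantized in steps of 1/n, so whenever `n·θ_pos < 1` (n ≤ 10 at the
default) a single substitution event at any seed position forces a
`diverged` call. For small families this makes the seed criterion very
conservative — a known limitation, visible in the simulation experiments
below, and the reason θ_pos is a prominent config value rather than a
constant.

## Distances and split networks

Jukes–Cantor distances use complete deletion: any column with a gap in any
row is removed for all pairs, then `d = −(3/4)·ln(1 − 4p/3)`. Proportions
at or above 0.74 are capped just below the transform's singularity at 3/4
with a saturation warning, so agglomeration always runs on finite
distances.

Neighbor-net builds a circular taxon ordering agglomeratively: clusters
(chains of at most two active nodes) are chosen by the neighbor-joining
criterion on average inter-cluster distances; a second selection picks the
actual nodes to link, counting the two chosen clusters' nodes as
individual units; linked chains are reduced three nodes at a time with the
standard 2/3–1/3 distance updates, and reductions are expanded in reverse
at the end to give the circular order. Split weights are then estimated by
ordinary least squares over the full circular split system (n(n−1)/2
interval splits), with non-negativity enforced by iteratively deleting
negative-weight splits and refitting — a deterministic approximation to
constrained NNLS that is exact on additive inputs and adequate at
gene-family scale (n ≲ 50); splits under 1e-8 are dropped. On additive
(tree) metrics the procedure recovers exactly the tree's splits with their
branch lengths and zero residual, which the test battery checks against
random trees. Networks serialize as NEXUS TAXA + SPLITS blocks (cycle and
weighted splits) readable by SplitsTree-style viewers; weights round-trip
through the package's own reader to 1e-10. Degenerate tree-like networks
are left in NEXUS/TSV form; no Newick export or graphical layout is
provided.

## The simulator and what passing tests mean

`synthetic_data` builds an ancestral hairpin with an explicit layout —
5' flank (5–15 nt), 22-nt 5'-arm mature (seed 2–8, anchor 13–16), loop
(8–20 nt), 22-nt star, 3' flank (5–15 nt) — where the star is the reverse
complement of the mature duplex body arranged so both duplex ends carry
2-nt 3' overhangs. Sequence composition is constrained (mature body over
{A,C,G}; 5' flank and loop over {A,C}; 3' flank poly-C) so no alternative
pairing can compete with the intended stem; each ancestor is verified by
folding and duplex-rule recovery, resampling on the rare failure. The
2-letter flank/loop alphabet matters: fully homopolymeric spacers make gap
placement within them arbitrary and introduce systematic one-column
misalignments at region boundaries.

Evolution is site-independent Jukes–Cantor with region-specific rates: on
a branch of length t, a site in region R substitutes with probability
`(3/4)(1 − e^(−4·r_R·t/3))`, the new base uniform over the three
alternatives. Loop indels are single-base Poisson events
(`loop_indel_rate·t·loop_len`, default rate 0.05/site/unit), insertions
and deletions equiprobable, with the loop kept ≥4 nt. Whole-hairpin
duplications fork an independently evolving paralog at internal edges with
probability `duplication_prob`; paralog loop and star rates are boosted
1.5× so multicopy precursors share matures but diverge elsewhere. Default
rates (seed 0.01 < anchor 0.02 < mature body 0.05 ≤ star ≤ loop 0.5,
flanks 0.3 substitutions/site/unit time) encode the biological regime
under study; `star_mode` ties the star to the mature body (`conserved`),
to the loop (`diverged`), or alternates (`mixed`). The default species
tree is a balanced ultrametric 8-leaf vertebrate tree of height 1 — a
desk-scale stand-in for a typical cross-vertebrate family; cohort
experiments use 50 such families and 100 replicates, sizes chosen to keep
full runs in the minutes range.

Because the simulator uses the same substitution model the analysis
assumes, passing tests demonstrate *self-consistency* — correct
bookkeeping, calibration of the JC machinery, recoverability of rate
orderings and star spans — not robustness to covarion-like rate shifts,
structure-constrained compensatory evolution, alignment error on real
flanks, isomiR heterogeneity, or database annotation noise.

Two simulation experiments quantify the granularity limitation noted
above, at the default thresholds with 8-species families:

- star-fate classification on the mixed cohort (conserved star rate 0.05
  vs diverged 0.5) reaches only ~0.5–0.6 accuracy, because nearly every
  truly conserved star family shows at least one substitution event
  somewhere in the 7 seed positions × 8 rows, and 1/8 > θ_pos; the mean
  substitution fraction alone separates the classes far better;
- per-replicate recovery of the seed < star < loop ordering holds in
  ~90% of families: a single pendant seed substitution contributes
  1/56 ≈ 0.018 to the 7-position seed mean, which exceeds the star mean in
  low-divergence draws.

Both effects shrink with family size (more rows, finer fractions) and are
properties of small-sample per-position statistics, not of the pipeline's
arithmetic (which matches an independent recount exactly).

## Determinism

Every stochastic component takes an explicit seed; presets carry fixed
default seeds so fixture bundles are byte-identical across runs. All
tie-breaks (traceback order, UPGMA agglomeration, consensus ties,
neighbor-net selection) are deterministic, and floating-point outputs are
serialized with fixed 6-decimal formatting, so rerunning a configuration
reproduces outputs byte for byte.
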