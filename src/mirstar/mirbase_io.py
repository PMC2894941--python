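"""Reading, writing and parsing miRBase-dialect miRNA records.

miRBase names encode a lot of structure: ``hsa-let-7a-1`` is species ``hsa``,
family stem ``let-7``, homologous variant ``a``, genomic copy ``1``;
``dre-miR-124*`` is a passenger (star) strand; ``hsa-miR-17-5p`` is the mature
product of the 5' arm.  This module parses that convention, normalizes
sequences to uppercase RNA, maps mature/star strands onto their hairpin
precursors (1-based inclusive coordinates throughout) and groups precursors
into gene families by stem.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaFormatError, MappingError, NameParseError

RNA_ALPHABET = frozenset("ACGU")

#: stem keywords that must not be mistaken for a species prefix
_STEM_WORDS = frozenset({"mir", "let", "lin", "bantam", "iab"})
_SPECIES_RE = re.compile(r"[a-z][a-z0-9]{2}")
_STEM_RE = re.compile(r"^(?P<base>[a-z]+(?:-\d+)?)(?P<variant>[a-z]*)(?:-(?P<copy>\d+))?$")


@dataclass(frozen=True)
class NameParts:
    """Decomposition of a miRBase-style identifier."""

    species: str  # 3-letter code, "unk" when absent
    stem: str  # family stem, e.g. "let-7", "mir-124"
    variant: str | None  # homologous gene letter, e.g. "a"
    copy: int | None  # genomic copy number for multicopy precursors
    arm: str  # "5p", "3p" or "unknown"
    star: bool  # True when the id carries the "*" marker


def parse_name(identifier: str) -> NameParts:
    """Parse a miRBase-dialect identifier into its naming components.

    >>> parse_name("hsa-let-7a-1")
    NameParts(species='hsa', stem='let-7', variant='a', copy=1, arm='unknown', star=False)
    """
    if not identifier or not identifier.strip():
        raise NameParseError("empty identifier")
    name = identifier.strip()
    star = name.endswith("*")
    if star:
        name = name[:-1]
    tokens = name.split("-")
    arm = "unknown"
    if tokens and tokens[-1].lower() in ("5p", "3p"):
        arm = tokens[-1].lower()
        tokens = tokens[:-1]
    species = "unk"
    if (
        len(tokens) > 1
        and _SPECIES_RE.fullmatch(tokens[0])
        and tokens[0] not in _STEM_WORDS
    ):
        species = tokens[0]
        tokens = tokens[1:]
    if not tokens:
        raise NameParseError(f"no stem in identifier {identifier!r}")
    residue = "-".join(tokens).lower()  # folds miR -> mir
    match = _STEM_RE.match(residue)
    if match is None:
        # non-standard stem (provisional ids): keep verbatim
        return NameParts(species, residue, None, None, arm, star)
    stem = match.group("base")
    variant = match.group("variant") or None
    copy = int(match.group("copy")) if match.group("copy") else None
    return NameParts(species, stem, variant, copy, arm, star)


def normalize_sequence(seq: str, allow_gap: bool = False) -> str:
    """Uppercase, DNA->RNA (T->U); validates the alphabet."""
    out = seq.upper().replace("T", "U")
    allowed = RNA_ALPHABET | ({"-"} if allow_gap else set())
    bad = set(out) - allowed
    if bad:
        raise FastaFormatError(f"non-RNA symbols {sorted(bad)} in sequence")
    return out


@dataclass(frozen=True)
class HairpinRecord:
    """One precursor (stem-loop) sequence with its parsed name."""

    id: str
    sequence: str
    species: str = "unk"
    stem: str = ""
    variant: str | None = None
    copy: int | None = None
    description: str = ""

    @classmethod
    def from_fasta(cls, identifier: str, sequence: str, description: str = "") -> "HairpinRecord":
        parts = parse_name(identifier)
        seq = normalize_sequence(sequence)
        if not seq:
            raise FastaFormatError(f"empty sequence for {identifier!r}")
        return cls(identifier, seq, parts.species, parts.stem, parts.variant, parts.copy, description)


@dataclass(frozen=True)
class MatureRecord:
    """A mature or star strand, optionally located on its hairpin.

    ``span`` is 1-based inclusive on the hairpin sequence.  ``role`` follows
    the naming convention: ids carrying the "*" marker are passenger (star)
    strands; ``dual`` marks hairpins whose both arms yield abundant products.
    """

    id: str
    sequence: str
    hairpin_id: str = ""
    role: str = "mature"  # mature | star | dual
    arm: str = "unknown"  # 5p | 3p | unknown
    span: tuple[int, int] | None = None
    multi_hit: bool = False

    @classmethod
    def from_fasta(cls, identifier: str, sequence: str) -> "MatureRecord":
        parts = parse_name(identifier)
        role = "star" if parts.star else "mature"
        return cls(identifier, normalize_sequence(sequence), role=role, arm=parts.arm)


@dataclass(frozen=True)
class FamilyGroup:
    """All precursors sharing one family stem (variants/copies collapsed)."""

    family_key: str
    members: tuple[str, ...]
    species_set: frozenset[str]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def _scan_for_empty_records(path: Path) -> None:
    """Raise a line-numbered error for headers with no sequence."""
    last_header_line = None
    have_seq = False
    saw_any = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            if last_header_line is not None and not have_seq:
                raise FastaFormatError(
                    f"{path}: header at line {last_header_line} has no sequence"
                )
            last_header_line = lineno
            have_seq = False
            saw_any = True
        elif line.strip():
            if last_header_line is None:
                raise FastaFormatError(f"{path}: sequence before any header at line {lineno}")
            have_seq = True
    if last_header_line is not None and not have_seq:
        raise FastaFormatError(f"{path}: header at line {last_header_line} has no sequence")
    if not saw_any:
        raise FastaFormatError(f"{path}: no FASTA records")


def read_fasta(path: str | Path, allow_gap: bool = False) -> list[FastaRecord]:
    """Read a (possibly wrapped) FASTA file, normalizing sequences to RNA.

    Order is preserved; the description after the first whitespace is kept.
    """
    path = Path(path)
    _scan_for_empty_records(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip()
        records.append(FastaRecord(rec.id, normalize_sequence(str(rec.seq), allow_gap), desc))
    return records


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write records (anything with .id/.sequence, or (id, seq) pairs)."""
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec[0], rec[1]
            desc = ""
        else:
            rid, seq = rec.id, rec.sequence
            desc = getattr(rec, "description", "")
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")


def load_hairpins(path: str | Path) -> list[HairpinRecord]:
    return [HairpinRecord.from_fasta(r.id, r.sequence, r.description) for r in read_fasta(path)]


def load_matures(path: str | Path) -> list[MatureRecord]:
    return [MatureRecord.from_fasta(r.id, r.sequence) for r in read_fasta(path)]


def map_mature_to_hairpin(mature: MatureRecord, hairpin: HairpinRecord) -> MatureRecord:
    """Locate a mature/star sequence on its hairpin (first exact occurrence).

    The arm is called from the span midpoint relative to the hairpin midpoint;
    multiple occurrences set ``multi_hit`` rather than failing (hairpins are
    short and internal repeats rare).
    """
    pos = hairpin.sequence.find(mature.sequence)
    if pos < 0:
        raise MappingError(
            f"sequence of {mature.id!r} does not occur on hairpin {hairpin.id!r}"
        )
    start, end = pos + 1, pos + len(mature.sequence)
    multi = hairpin.sequence.find(mature.sequence, pos + 1) >= 0
    mid = (start + end) / 2.0
    arm = "5p" if mid <= (len(hairpin.sequence) + 1) / 2.0 else "3p"
    return replace(mature, hairpin_id=hairpin.id, span=(start, end), arm=arm, multi_hit=multi)


def group_families(hairpins: Sequence[HairpinRecord]) -> list[FamilyGroup]:
    """Partition precursors into gene families by stem.

    The family key collapses variant letters and copy numbers
    (``hsa-let-7a-1`` and ``mmu-let-7c`` both belong to ``let-7``).
    """
    buckets: dict[str, list[HairpinRecord]] = {}
    for hp in hairpins:
        buckets.setdefault(hp.stem, []).append(hp)
    return [
        FamilyGroup(
            key,
            tuple(h.id for h in members),
            frozenset(h.species for h in members),
        )
        for key, members in sorted(buckets.items())
    ]


def annotation_table(matures: Sequence[MatureRecord]) -> pd.DataFrame:
    """Mature-on-hairpin annotation table (1-based inclusive coordinates)."""
    rows = []
    for m in matures:
        start, end = m.span if m.span else (pd.NA, pd.NA)
        rows.append(
            {
                "hairpin_id": m.hairpin_id,
                "mature_id": m.id,
                "role": m.role,
                "arm": m.arm,
                "start": start,
                "end": end,
            }
        )
    return pd.DataFrame(rows, columns=["hairpin_id", "mature_id", "role", "arm", "start", "end"])


def write_annotation(matures: Sequence[MatureRecord], path: str | Path) -> None:
    annotation_table(matures).to_csv(path, sep="\t", index=False)
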