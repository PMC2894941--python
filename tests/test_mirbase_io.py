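"""Identifier parsing, FASTA round-trips and gene-family grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirstar import errors, mirbase_io
from mirstar.mirbase_io import (
    HairpinRecord,
    MatureRecord,
    group_families,
    map_mature_to_hairpin,
    parse_name,
    read_fasta,
    write_fasta,
)


@pytest.mark.parametrize(
    "identifier,expected",
    [
        ("hsa-let-7a-1", ("hsa", "let-7", "a", 1, "unknown", False)),
        ("hsa-miR-17-5p", ("hsa", "mir-17", None, None, "5p", False)),
        ("dre-miR-124*", ("dre", "mir-124", None, None, "unknown", True)),
        ("sp1-mir-900-1", ("sp1", "mir-900", None, 1, "unknown", False)),
        ("mmu-mir-125b-1", ("mmu", "mir-125", "b", 1, "unknown", False)),
        ("hsa-miR-199a-3p", ("hsa", "mir-199", "a", None, "3p", False)),
        ("mir-124", ("unk", "mir-124", None, None, "unknown", False)),
        ("let-7", ("unk", "let-7", None, None, "unknown", False)),
        ("dme-bantam", ("dme", "bantam", None, None, "unknown", False)),
    ],
)
def test_parse_name(identifier, expected):
    parts = parse_name(identifier)
    assert (parts.species, parts.stem, parts.variant, parts.copy, parts.arm, parts.star) == expected


def test_parse_name_empty_errors():
    with pytest.raises(errors.NameParseError):
        parse_name("")


def _stringify(parts):
    out = "" if parts.species == "unk" else parts.species + "-"
    out += parts.stem
    if parts.variant:
        out += parts.variant
    if parts.copy is not None:
        out += f"-{parts.copy}"
    if parts.arm != "unknown":
        out += f"-{parts.arm}"
    if parts.star:
        out += "*"
    return out


@pytest.mark.parametrize(
    "identifier",
    ["hsa-let-7a-1", "hsa-miR-17-5p", "dre-miR-124*", "mmu-mir-125b-1",
     "hsa-miR-199a-3p", "gga-mir-142", "xtr-let-7f-2"],
)
def test_parse_name_idempotent_on_stringification(identifier):
    first = parse_name(identifier)
    again = parse_name(_stringify(first))
    assert again == first


def test_read_fasta_normalizes_and_keeps_order(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text(">x some description\nacgt\n>b\nGU\n")
    records = read_fasta(path)
    assert [(r.id, r.sequence) for r in records] == [("x", "ACGU"), ("b", "GU")]
    assert records[0].description == "some description"


def test_read_fasta_header_only_errors_with_line_number(tmp_path):
    path = tmp_path / "bad.fa"
    path.write_text(">a\nACGU\n>empty\n>c\nGG\n")
    with pytest.raises(errors.FastaFormatError, match="line 3"):
        read_fasta(path)


def test_read_fasta_rejects_non_rna(tmp_path):
    path = tmp_path / "bad.fa"
    path.write_text(">a\nACGX\n")
    with pytest.raises(errors.FastaFormatError):
        read_fasta(path)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.from_regex(r"[a-z]{3}-mir-[0-9]{1,3}", fullmatch=True),
            st.text(alphabet="ACGU", min_size=1, max_size=120),
        ),
        min_size=1,
        max_size=6,
        unique_by=lambda t: t[0],
    )
)
def test_fasta_round_trip(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("fa") / "rt.fa"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [(r.id, r.sequence) for r in back] == records


def test_map_mature_to_hairpin_examples():
    hp = HairpinRecord.from_fasta("hsa-mir-1", "AAGGGAA")
    m = MatureRecord.from_fasta("hsa-miR-1", "GGG")
    mapped = map_mature_to_hairpin(m, hp)
    assert mapped.span == (3, 5)
    assert mapped.arm == "5p"
    assert mapped.hairpin_id == "hsa-mir-1"
    # mature equal to hairpin
    full = map_mature_to_hairpin(MatureRecord.from_fasta("hsa-miR-1", "AAGGGAA"), hp)
    assert full.span == (1, 7) and full.arm == "5p"
    # span invariant: hairpin subsequence equals the mature sequence
    s, e = mapped.span
    assert hp.sequence[s - 1 : e] == mapped.sequence


def test_map_mature_no_occurrence_errors():
    hp = HairpinRecord.from_fasta("hsa-mir-1", "AAAA")
    with pytest.raises(errors.MappingError, match="hsa-miR-1"):
        map_mature_to_hairpin(MatureRecord.from_fasta("hsa-miR-1", "UU"), hp)


def test_map_mature_multi_hit_flagged():
    hp = HairpinRecord.from_fasta("hsa-mir-1", "GGAUGGAU")
    mapped = map_mature_to_hairpin(MatureRecord.from_fasta("hsa-miR-1", "GGAU"), hp)
    assert mapped.span == (1, 4)
    assert mapped.multi_hit


def test_group_families_collapses_variants_and_copies():
    ids = ["hsa-let-7a-1", "hsa-let-7a-2", "mmu-let-7c", "hsa-mir-124-1", "dre-mir-124"]
    hps = [HairpinRecord.from_fasta(i, "ACGU") for i in ids]
    fams = group_families(hps)
    assert [f.family_key for f in fams] == ["let-7", "mir-124"]
    let7, mir124 = fams
    assert len(let7.members) == 3
    assert mir124.species_set == frozenset({"hsa", "dre"})


def test_group_families_is_a_partition(rng):
    stems = ["mir-1", "mir-21", "let-7", "mir-125"]
    ids = [
        f"{sp}-{stem}{var}" for sp in ("hsa", "mmu", "dre")
        for stem, var in zip(stems, ("", "a", "b-1", ""))
    ]
    hps = [HairpinRecord.from_fasta(i, "ACGU") for i in set(ids)]
    fams = group_families(hps)
    seen = [m for f in fams for m in f.members]
    assert sorted(seen) == sorted(h.id for h in hps)
    for fam in fams:
        for member in fam.members:
            assert parse_name(member).stem == fam.family_key


def test_singleton_family():
    fams = group_families([HairpinRecord.from_fasta("hsa-mir-9", "ACGU")])
    assert len(fams) == 1 and fams[0].members == ("hsa-mir-9",)


def test_annotation_table_columns(tmp_path):
    hp = HairpinRecord.from_fasta("hsa-mir-1", "AAGGGAA")
    mapped = map_mature_to_hairpin(MatureRecord.from_fasta("hsa-miR-1", "GGG"), hp)
    table = mirbase_io.annotation_table([mapped])
    assert list(table.columns) == ["hairpin_id", "mature_id", "role", "arm", "start", "end"]
    assert table.iloc[0]["start"] == 3 and table.iloc[0]["end"] == 5
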