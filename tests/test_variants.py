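"""Variant grammar, tables, and structure-presence mapping."""

import pytest
from hypothesis import given, settings, strategies as st

from strucmap import fixtures as fx
from strucmap.reference_map import (
    align_chain_to_reference,
    renumber_chain,
)
from strucmap.variants import (
    VariantSyntaxError,
    map_variant_presence,
    parse_variant,
    read_variant_table,
    variants_by_position,
)

# every variant type in 1-letter and 3-letter notation
GRAMMAR_CASES = [
    ("V600E", "missense", (600, 600), "V", "E"),
    ("Val600Glu", "missense", (600, 600), "V", "E"),
    ("p.V600E", "missense", (600, 600), "V", "E"),
    ("R130*", "nonsense", (130, 130), "R", "*"),
    ("Arg130Ter", "nonsense", (130, 130), "R", "*"),
    ("R130X", "nonsense", (130, 130), "R", "*"),
    ("E746_A750del", "deletion", (746, 750), "EA", ""),
    ("Glu746_Ala750del", "deletion", (746, 750), "EA", ""),
    ("V600del", "deletion", (600, 600), "VV", ""),
    ("D770_N771insNPG", "insertion", (770, 771), "DN", "NPG"),
    ("Asp770_Asn771insAsnProGly", "insertion", (770, 771), "DN", "NPG"),
    ("A767_V769dup", "duplication", (767, 769), "AV", ""),
    ("Ala767_Val769dup", "duplication", (767, 769), "AV", ""),
    ("N1068fs", "frameshift", (1068, 1068), "N", ""),
    ("Asn1068fs", "frameshift", (1068, 1068), "N", ""),
    ("N1068fs*4", "frameshift", (1068, 1068), "N", ""),
]


@pytest.mark.parametrize("raw,vtype,positions,ref_aa,alt_aa", GRAMMAR_CASES)
def test_grammar(raw, vtype, positions, ref_aa, alt_aa):
    rec = parse_variant(raw)
    assert rec.type == vtype
    assert rec.positions == positions
    assert rec.ref_aa == ref_aa
    assert rec.alt_aa == alt_aa


@pytest.mark.parametrize("raw", [r for r, *_ in GRAMMAR_CASES])
def test_canonical_round_trip(raw):
    rec = parse_variant(raw)
    canon = rec.canonical()
    rec2 = parse_variant(canon)
    assert rec2.canonical() == canon
    assert (rec2.type, rec2.positions, rec2.ref_aa, rec2.alt_aa) == \
           (rec.type, rec.positions, rec.ref_aa, rec.alt_aa)


@pytest.mark.parametrize("raw", [
    "", "600E", "V600", "?bogus?", "V0E", "E750_A746del", "Xyz600Glu",
    "D770_N775insNPG",  # non-adjacent insertion flanks
])
def test_rejects_bad_strings(raw):
    with pytest.raises(VariantSyntaxError):
        parse_variant(raw)


AA = "ACDEFGHIKLMNPQRSTVWY"


@settings(derandomize=True, max_examples=100)
@given(st.sampled_from(AA), st.integers(1, 5000), st.sampled_from(AA))
def test_missense_round_trip_property(ref_aa, pos, alt_aa):
    raw = f"{ref_aa}{pos}{alt_aa}"
    if ref_aa == alt_aa:
        return  # synonymous: not a missense record
    rec = parse_variant(raw)
    assert rec.canonical() == raw


def test_variant_table_with_rejects(tmp_path):
    path = tmp_path / "vars.tsv"
    fx.make_variant_table(["V600E", "R130*", "E746_A750del", "N1068fs"],
                          path, malformed=["*bad*"],
                          ptm_rows=[("S473D", "phosphosite")])
    records, rejects = read_variant_table(path)
    assert len(records) == 5
    assert len(rejects) == 1 and "*bad*" in rejects[0].raw
    ptm = [r for r in records if r.ptm]
    assert len(ptm) == 1 and ptm[0].canonical() == "S473D"
    effects = {r.canonical(): r.effect for r in records}
    assert effects["V600E"] == "activating"


def test_variant_table_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("raw\teffect\nV600E\tactivating\n")
    with pytest.raises(ValueError):
        read_variant_table(path)


def test_empty_variant_table(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert read_variant_table(path) == ([], [])


def _renumbered_with_gap(tmp_path, seed=21, ref_length=80):
    ref = fx.make_reference(fx.FixtureSpec(seed=seed, ref_length=ref_length))
    lo = next(l for l in range(40, 60)
              if fx.deletion_is_unambiguous(ref.sequence, l, l + 2))
    spec = fx.FixtureSpec(seed=seed, ref_length=ref_length,
                          deleted_ranges=[(lo, lo + 2)])
    paths, _ = fx.make_structure(spec, ref, tmp_path, ("pdb",))
    from strucmap.io_structures import read_structure
    model = read_structure(paths["pdb"])
    aln = align_chain_to_reference(model.chains[0], ref)
    return renumber_chain(model.chains[0], aln, ref=ref), ref, (lo, lo + 2)


def test_presence_full_partial_absent(tmp_path):
    rc, ref, (glo, ghi) = _renumbered_with_gap(tmp_path)
    # resolved missense -> full
    full = map_variant_presence(parse_variant(f"{ref.at(10)}10A"
                                              if ref.at(10) != "A" else "A10V"), rc)
    assert full.status == "full"
    # deletion spanning the unresolved gap -> partial with exact absent set
    v = parse_variant(f"{ref.at(glo - 1)}{glo - 1}_{ref.at(ghi)}{ghi}del")
    p = map_variant_presence(v, rc)
    assert p.status == "partial"
    assert p.absent_positions == list(range(glo, ghi + 1))
    assert p.present_positions == [glo - 1]
    # beyond the chain span -> absent
    far = map_variant_presence(parse_variant("K500*"), rc)
    assert far.status == "absent"


def test_presence_partition_matches_brute_force(tmp_path):
    rc, ref, _gap = _renumbered_with_gap(tmp_path, seed=22)
    resolved = rc.resolved_positions()
    for raw in [f"{ref.at(5)}5fs", f"{ref.at(30)}30*",
                f"{ref.at(41)}41_{ref.at(50)}50del",
                f"{ref.at(70)}70_{ref.at(71)}71insAAA"]:
        v = parse_variant(raw)
        p = map_variant_presence(v, rc)
        pos = set(v.position_list())
        assert set(p.present_positions) == pos & resolved
        assert set(p.absent_positions) == pos - resolved
        assert set(p.present_positions) | set(p.absent_positions) == pos
        assert not (set(p.present_positions) & set(p.absent_positions))


def test_reference_mismatch_warning(tmp_path):
    rc, ref, _gap = _renumbered_with_gap(tmp_path, seed=23)
    wrong = "A" if ref.at(10) != "A" else "C"
    v = parse_variant(f"{wrong}10{'V' if wrong != 'V' else 'L'}")
    p = map_variant_presence(v, rc, ref.sequence)
    assert p.warnings and "reference-mismatch" in p.warnings[0]


def test_variants_by_position_covers_interval():
    v = parse_variant("E746_A750del")
    by_pos = variants_by_position([v])
    assert set(by_pos) == {746, 747, 748, 749, 750}
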