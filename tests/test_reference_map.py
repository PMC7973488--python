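"""Chain-to-reference alignment, renumbering, discrepancy detection, filters."""

import pytest

from strucmap import fixtures as fx
from strucmap.io_structures import StructureHeader, StructureModel
from strucmap.reference_map import (
    AlignmentError,
    ChainAlignment,
    Discrepancies,
    FilterConfig,
    MutatedResidue,
    RenumberedChain,
    align_chain_to_reference,
    apply_structure_filters,
    detect_discrepancies,
    renumber_chain,
)


def _chain_from_fixture(spec, tmp_path):
    from strucmap.io_structures import read_structure

    ref = fx.make_reference(spec)
    paths, gt = fx.make_structure(spec, ref, tmp_path, ("pdb",))
    model = read_structure(paths["pdb"])
    return model, model.chains[0], ref, gt


def test_exact_subsequence_alignment(tmp_path):
    # chain = ref[25..54]: perfect identity, correct span, zero gaps
    spec = fx.FixtureSpec(seed=11, ref_length=80, chain_span=(25, 54))
    _m, chain, ref, _gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    assert aln.identity == 1.0
    assert aln.ref_span == (25, 54)
    assert all(k is not None and p is not None for k, p in aln.aligned_pairs)


def test_full_length_alignment(tmp_path):
    spec = fx.FixtureSpec(seed=12, ref_length=60)
    _m, chain, ref, _gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    assert aln.identity == 1.0
    assert aln.ref_span == (1, 60)


def test_single_substitution_identity(tmp_path):
    # chain = ref[10..40] with one substitution at 20 -> identity 30/31
    spec = fx.FixtureSpec(seed=13, ref_length=60, chain_span=(10, 40),
                          substitutions=[(20, "")])
    _m, chain, ref, gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    assert aln.identity == pytest.approx(30 / 31)
    disc = detect_discrepancies(aln, chain, ref)
    assert [(m.ref_pos, m.ref_aa, m.chain_aa) for m in disc.mutated] == [
        (p, o, n) for p, o, n, _ in gt.substitutions]


def test_identity_floor_rejects_unrelated(tmp_path):
    spec = fx.FixtureSpec(seed=14, ref_length=80)
    _m, chain, _ref, _gt = _chain_from_fixture(spec, tmp_path)
    other = fx.make_reference(fx.FixtureSpec(seed=999, ref_length=80),
                              accession="OTHER0001")
    with pytest.raises(AlignmentError):
        align_chain_to_reference(chain, other, min_identity=0.9)


def test_declared_vs_undeclared_mutations(tmp_path):
    # two substitutions, one declared in the header
    ref = fx.make_reference(fx.FixtureSpec(seed=15, ref_length=100))
    for attempt in range(50):
        spec = fx.FixtureSpec(seed=15 * 1000 + attempt, ref_length=100,
                              substitutions=[(20, ""), (60, "")],
                              declared_fraction=0.5)
        records, gt = fx.build_chain_records(spec, ref)
        if sum(d for _p, _o, _n, d in gt.substitutions) == 1:
            break
    else:
        pytest.fail("no half-declared fixture found")
    paths, gt = fx.make_structure(spec, ref, tmp_path, ("pdb",))
    from strucmap.io_structures import read_structure
    model = read_structure(paths["pdb"])
    aln = align_chain_to_reference(model.chains[0], ref)
    disc = detect_discrepancies(aln, model.chains[0], ref, model.header)
    assert len(disc.mutated) == 2
    assert sum(m.declared for m in disc.mutated) == 1
    undeclared = [m for m in disc.mutated if not m.declared]
    assert len(undeclared) == 1


def test_unresolved_gap_reported_missing(tmp_path):
    ref = fx.make_reference(fx.FixtureSpec(seed=16, ref_length=80))
    lo = next(l for l in range(40, 60) if fx.deletion_is_unambiguous(ref.sequence, l, l + 4))
    spec = fx.FixtureSpec(seed=16, ref_length=80, deleted_ranges=[(lo, lo + 4)])
    paths, _ = fx.make_structure(spec, ref, tmp_path, ("pdb",))
    from strucmap.io_structures import read_structure
    model = read_structure(paths["pdb"])
    aln = align_chain_to_reference(model.chains[0], ref)
    disc = detect_discrepancies(aln, model.chains[0], ref)
    assert sorted(m.ref_pos for m in disc.missing) == list(range(lo, lo + 5))
    assert disc.mutated == [] and disc.inserted == []


def test_offset_renumbering(tmp_path):
    # author numbers 1..30 for ref 25..54: mapping adds +24
    spec = fx.FixtureSpec(seed=17, ref_length=80, chain_span=(25, 54),
                          chain_offset=-24)
    _m, chain, ref, _gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    rc = renumber_chain(chain, aln, ref=ref)
    assert {k[1]: p for k, p in rc.mapping.items()} == {
        i: i + 24 for i in range(1, 31)}
    assert rc.missing_fraction == 0.0 and rc.kept


def test_identity_mapping_round_trip(tmp_path):
    spec = fx.FixtureSpec(seed=18, ref_length=40)
    _m, chain, ref, _gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    rc = renumber_chain(chain, aln, ref=ref)
    assert all(k[1] == p for k, p in rc.mapping.items())


def test_mapping_strictly_increasing(tmp_path):
    spec = fx.random_fixture_spec(123)
    ref = fx.make_reference(spec)
    paths, _ = fx.make_structure(spec, ref, tmp_path, ("pdb",))
    from strucmap.io_structures import read_structure
    model = read_structure(paths["pdb"])
    aln = align_chain_to_reference(model.chains[0], ref)
    rc = renumber_chain(model.chains[0], aln, ref=ref)
    ordered = [rc.mapping[r.key] for r in model.chains[0].residues
               if rc.mapping.get(r.key) is not None]
    assert ordered == sorted(ordered)
    assert len(set(ordered)) == len(ordered)


def test_insertion_ordinal_labels(tmp_path):
    spec = fx.FixtureSpec(seed=19, ref_length=60, inserted_runs=[(30, 2)])
    _m, chain, ref, gt = _chain_from_fixture(spec, tmp_path)
    aln = align_chain_to_reference(chain, ref)
    rc = renumber_chain(chain, aln, ref=ref)
    ins_keys = [tuple(k) for k in gt.inserted_keys]
    assert [rc.mapping[k] for k in ins_keys] == [None, None]
    assert [rc.insertion_labels[k] for k in ins_keys] == ["30+1", "30+2"]


def _fake_alignment(span, missing_positions, ref_len=100):
    lo, hi = span
    pairs = []
    for p in range(lo, hi + 1):
        if p in missing_positions:
            pairs.append((None, p))
        else:
            pairs.append((("A", p, ""), p))
    return ChainAlignment("A", "REF", pairs, 1.0, span, 100.0, ref_len)


def _chain_stub():
    from strucmap.io_structures import ChainModel
    return ChainModel("A", [])


def test_missing_fraction_boundary_strict():
    """span 10 with 2 missing -> kept; 3 missing -> dropped (strict < 0.30)."""
    aln2 = _fake_alignment((1, 10), {3, 5})
    rc2 = renumber_chain(_chain_stub(), aln2)
    assert rc2.missing_fraction == pytest.approx(0.2) and rc2.kept
    aln3 = _fake_alignment((1, 10), {3, 5, 7})
    rc3 = renumber_chain(_chain_stub(), aln3)
    assert rc3.missing_fraction == pytest.approx(0.3) and not rc3.kept


def _rc_with_mutations(n, kept=True):
    disc = Discrepancies(
        mutated=[MutatedResidue(i + 1, "A", "V", ("A", i + 1, "")) for i in range(n)])
    return RenumberedChain("A", "REF", 100, {("A", 1, ""): 1}, {}, disc,
                           (1, 50), 0.0, kept)


def _model(entry_id="XXXX"):
    return StructureModel(StructureHeader(entry_id=entry_id), [], [])


def test_mutation_count_boundary():
    """10 mutations kept; 11 dropped; 11 + override kept (strictly > 10)."""
    cfg = FilterConfig()
    assert apply_structure_filters(_model(), [_rc_with_mutations(10)], cfg).keep
    d11 = apply_structure_filters(_model(), [_rc_with_mutations(11)], cfg)
    assert not d11.keep and any("mutation-count" in r for r in d11.reasons)
    cfg_ov = FilterConfig(allow_override=frozenset({"GN11"}))
    d_ov = apply_structure_filters(_model("GN11"), [_rc_with_mutations(12)], cfg_ov)
    assert d_ov.keep and d_ov.override_used


def test_no_kept_chain_drops_structure():
    d = apply_structure_filters(_model(), [_rc_with_mutations(0, kept=False)],
                                FilterConfig())
    assert not d.keep and any("no-chain-kept" in r for r in d.reasons)


def test_missing_fraction_monotone():
    fracs = []
    for n_missing in range(0, 8):
        aln = _fake_alignment((1, 20), set(range(3, 3 + n_missing)))
        fracs.append(renumber_chain(_chain_stub(), aln).missing_fraction)
    assert fracs == sorted(fracs)
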