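"""Synthetic, fully-known test inputs: coordinate files, reference
sequences, ortholog alignments, variant tables and ligand dictionaries,
with injected and *recorded* perturbations.

Every generator is a pure function of a seeded :class:`FixtureSpec`, so the
exact set of substitutions, deletions and insertions written into a
structure is known and can be compared against what the curation pipeline
recovers.  Chains are ideal α-helices (1.5 Å rise, 100° turn, pseudo
side-chain atom); contact-analysis scenes place chemically typed residue
fragments at explicit coordinates instead.

Edits are placed with a minimum separation and away from chain termini, and
inserted residues are chosen to differ from the flanking reference window,
so the optimal chain-to-reference alignment is unique and recovery of the
injected edit sets is exact rather than ambiguous.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from . import _aa
from .io_structures import (
    Atom,
    ChainModel,
    LigandEntry,
    Method,
    Residue,
    StructureHeader,
    StructureModel,
)
from .reference_map import ReferenceSequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_METHOD_TO_EXPDTA = {
    Method.XRAY: "X-RAY DIFFRACTION",
    Method.NEUTRON: "NEUTRON DIFFRACTION",
    Method.NMR: "SOLUTION NMR",
    Method.FIBER: "FIBER DIFFRACTION",
    Method.CRYOEM: "ELECTRON MICROSCOPY",
    Method.MODEL: "THEORETICAL MODEL",
}


class FixtureSpecError(ValueError):
    pass


@dataclass
class LigandFixture:
    comp_id: str
    center: tuple[float, float, float]
    n_atoms: int = 1


@dataclass
class PartnerChainFixture:
    chain_id: str = "B"
    length: int = 40
    offset_xyz: tuple[float, float, float] = (15.0, 0.0, 0.0)


@dataclass
class MsaMemberSpec:
    organism: str
    accession: str
    identity_target: float = 1.0
    reviewed: bool = False
    gap_ranges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class FixtureSpec:
    seed: int = 0
    ref_length: int = 150
    entry_id: str = "FX01"
    chain_id: str = "A"
    chain_span: Optional[tuple[int, int]] = None  # reference positions, default full
    chain_offset: int = 0  # author number = ref_pos + offset
    substitutions: list[tuple[int, str]] = field(default_factory=list)  # (ref_pos, new_aa)
    deleted_ranges: list[tuple[int, int]] = field(default_factory=list)
    inserted_runs: list[tuple[int, int]] = field(default_factory=list)  # (after_ref_pos, length)
    declared_fraction: float = 1.0
    method: Method = Method.XRAY
    resolution: Optional[float] = 1.8
    r_work: Optional[float] = 0.18
    r_free: Optional[float] = 0.21
    ligands: list[LigandFixture] = field(default_factory=list)
    n_waters: int = 0
    partner_chain: Optional[PartnerChainFixture] = None
    msa_members: list[MsaMemberSpec] = field(default_factory=list)
    variants: list[str] = field(default_factory=list)

    def validate(self, ref_length: Optional[int] = None) -> None:
        L = ref_length or self.ref_length
        touched: set[int] = set()

        def claim(lo: int, hi: int, what: str) -> None:
            if lo < 1 or hi > L:
                raise FixtureSpecError(f"{what} [{lo},{hi}] outside reference 1..{L}")
            span = set(range(lo, hi + 1))
            if span & touched:
                raise FixtureSpecError(f"overlapping edits at {what} [{lo},{hi}]")
            touched.update(span)

        for pos, _aa_new in self.substitutions:
            claim(pos, pos, "substitution")
        for lo, hi in self.deleted_ranges:
            claim(lo, hi, "deletion")
        for pos, _n in self.inserted_runs:
            claim(pos, pos, "insertion anchor")


@dataclass
class GroundTruth:
    """Machine-readable record of exactly what was injected."""
    entry_id: str
    chain_id: str
    offset: int
    span: tuple[int, int]
    substitutions: list[tuple[int, str, str, bool]]  # (ref_pos, old, new, declared)
    deleted_positions: list[int]
    declared_deleted: list[int]
    inserted_keys: list[tuple[str, int, str]]  # author keys
    declared_inserted: list[tuple[str, int, str]]

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# reference sequences
# ---------------------------------------------------------------------------

def make_reference(spec: FixtureSpec, accession: str = "REF00001",
                   gene: str = "GENE1") -> ReferenceSequence:
    """Deterministic pseudo-random reference sequence over the 20 amino acids."""
    if spec.ref_length < 1:
        raise FixtureSpecError("ref_length must be >= 1")
    rng = random.Random(f"ref:{spec.seed}")
    seq = "".join(rng.choice(AA20) for _ in range(spec.ref_length))
    return ReferenceSequence(accession=accession, gene=gene, sequence=seq, reviewed=True)


def write_reference_fasta(ref: ReferenceSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.accession} gene={ref.gene}"
                 f"{' reviewed=yes' if ref.reviewed else ''}\n")
        for i in range(0, len(ref.sequence), 60):
            fh.write(ref.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5     # Å per residue
_HELIX_TURN = 100.0   # degrees per residue
_HELIX_RADIUS = 2.3   # Å (gives ~3.8 Å CA-CA)


def _helix_atoms(i: int, res3: str, origin: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Backbone + pseudo side-chain atom positions for helix index i."""
    phi = math.radians(_HELIX_TURN * i)
    u = np.array([math.cos(phi), math.sin(phi), 0.0])       # radial
    t = np.array([-math.sin(phi), math.cos(phi), 0.0])      # tangential
    z = np.array([0.0, 0.0, 1.0])
    ca = origin + _HELIX_RADIUS * u + np.array([0, 0, _HELIX_RISE * i])
    atoms = [
        ("N", "N", ca - 1.2 * t - 0.4 * z),
        ("CA", "C", ca),
        ("C", "C", ca + 1.2 * t + 0.4 * z),
        ("O", "O", ca + 1.2 * t + 0.4 * z + 1.2 * u),
    ]
    if res3 != "GLY":
        atoms.append(("CB", "C", ca + 1.5 * u))
    return atoms


def _pick_insert_aa(rng: random.Random, ref_seq: str, anchor: int, run_len: int) -> str:
    """Residue letter distinct from the reference window around the insertion
    point, so gap placement in the optimal alignment cannot slide."""
    lo = max(0, anchor - run_len - 2)
    hi = min(len(ref_seq), anchor + run_len + 3)
    forbidden = set(ref_seq[lo:hi])
    choices = [a for a in AA20 if a not in forbidden]
    return rng.choice(choices or list(AA20))


def build_chain_records(spec: FixtureSpec, ref: ReferenceSequence):
    """The residue list (ref_pos|None, author_seq, icode, one_letter) for the
    chain, plus the ground truth of the edits applied."""
    spec.validate(len(ref))
    rng = random.Random(f"struct:{spec.seed}")
    span = spec.chain_span or (1, len(ref))
    lo, hi = span
    if not (1 <= lo <= hi <= len(ref)):
        raise FixtureSpecError(f"chain span {span} outside reference")
    deleted = set()
    for dlo, dhi in spec.deleted_ranges:
        deleted.update(range(dlo, dhi + 1))
    subs = dict(spec.substitutions)
    ins_by_anchor = dict(spec.inserted_runs)

    records: list[tuple[Optional[int], int, str, str]] = []
    gt_subs: list[tuple[int, str, str, bool]] = []
    gt_ins: list[tuple[str, int, str]] = []
    for pos in range(lo, hi + 1):
        if pos in deleted:
            continue
        aa = ref.at(pos)
        if pos in subs:
            new = subs[pos]
            if not new or new == aa:
                new = rng.choice([a for a in AA20 if a != aa])
            declared = rng.random() < spec.declared_fraction
            gt_subs.append((pos, aa, new, declared))
            aa = new
        records.append((pos, pos + spec.chain_offset, "", aa))
        if pos in ins_by_anchor:
            run_len = ins_by_anchor[pos]
            for k in range(run_len):
                icode = chr(ord("A") + k)
                aa_ins = _pick_insert_aa(rng, ref.sequence, pos, run_len)
                records.append((None, pos + spec.chain_offset, icode, aa_ins))
                gt_ins.append((spec.chain_id, pos + spec.chain_offset, icode))

    declared_ins = [k for k in gt_ins if rng.random() < spec.declared_fraction]
    deleted_in_span = sorted(p for p in deleted if lo <= p <= hi)
    declared_del = [p for p in deleted_in_span if rng.random() < spec.declared_fraction]
    gt = GroundTruth(
        entry_id=spec.entry_id,
        chain_id=spec.chain_id,
        offset=spec.chain_offset,
        span=span,
        substitutions=gt_subs,
        deleted_positions=deleted_in_span,
        declared_deleted=declared_del,
        inserted_keys=gt_ins,
        declared_inserted=declared_ins,
    )
    return records, gt


def _build_gemmi_structure(spec: FixtureSpec, records, ref: ReferenceSequence) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = spec.entry_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain_id)
    origin = np.zeros(3)
    for i, (ref_pos, author, icode, aa) in enumerate(records):
        res3 = _aa.AA_1TO3[aa]
        res = gemmi.Residue()
        res.name = res3
        res.seqid = gemmi.SeqId(author, icode or " ")
        res.het_flag = "A"
        for name, elem, xyz in _helix_atoms(i, res3, origin):
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(elem)
            a.pos = gemmi.Position(*xyz)
            a.occ = 1.0
            a.b_iso = 20.0
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)

    if spec.partner_chain is not None:
        pc = spec.partner_chain
        rng = random.Random(f"partner:{spec.seed}")
        pchain = gemmi.Chain(pc.chain_id)
        shift = np.array(pc.offset_xyz)
        for i in range(pc.length):
            aa = rng.choice(AA20)
            res3 = _aa.AA_1TO3[aa]
            res = gemmi.Residue()
            res.name = res3
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            for name, elem, xyz in _helix_atoms(i, res3, shift):
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(elem)
                a.pos = gemmi.Position(*xyz)
                a.occ = 1.0
                a.b_iso = 25.0
                res.add_atom(a)
            pchain.add_residue(res)
        model.add_chain(pchain)

    het = gemmi.Chain("L")
    lig_seq = 200
    for lig in spec.ligands:
        res = gemmi.Residue()
        res.name = lig.comp_id
        res.seqid = gemmi.SeqId(lig_seq, " ")
        res.het_flag = "H"
        cx, cy, cz = lig.center
        for j in range(lig.n_atoms):
            a = gemmi.Atom()
            a.name = f"C{j + 1}"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(cx + 0.9 * j, cy, cz)
            a.occ = 1.0
            a.b_iso = 30.0
            res.add_atom(a)
        het.add_residue(res)
        lig_seq += 1
    for w in range(spec.n_waters):
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(300 + w, " ")
        res.het_flag = "H"
        a = gemmi.Atom()
        a.name = "O"
        a.element = gemmi.Element("O")
        a.pos = gemmi.Position(30.0 + 3.0 * w, 30.0, 30.0)
        a.occ = 1.0
        a.b_iso = 40.0
        res.add_atom(a)
        het.add_residue(res)
    if len(het) > 0:
        model.add_chain(het)

    st.add_model(model)
    st.setup_entities()
    return st


def _pdb_header_lines(spec: FixtureSpec, gt: GroundTruth, ref: ReferenceSequence) -> list[str]:
    lines = [f"HEADER    {'PROTEIN FIXTURE':<40}{'01-JAN-20':<9}   {spec.entry_id:<4}"]
    lines.append(f"EXPDTA    {_METHOD_TO_EXPDTA[spec.method]}")
    if spec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {spec.resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    if spec.r_work is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {spec.r_work:.3f}")
    if spec.r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : {spec.r_free:.3f}")
    declared_missing = gt.declared_deleted
    if declared_missing:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for pos in declared_missing:
            res3 = _aa.AA_1TO3[ref.at(pos)]
            lines.append(f"REMARK 465     {res3:>3} {spec.chain_id:1} {pos + spec.chain_offset:>5}")
    for pos, old, new, declared in gt.substitutions:
        if not declared:
            continue
        res3 = _aa.AA_1TO3[new]
        ref3 = _aa.AA_1TO3[old]
        author = pos + spec.chain_offset
        lines.append(
            f"SEQADV {spec.entry_id:<4} {res3:>3} {spec.chain_id:1} {author:>4}  "
            f"{'UNP':<4} {ref.accession:<9} {ref3:>3} {pos:>5} ENGINEERED MUTATION"
        )
    for chain_id, author, icode in gt.declared_inserted:
        lines.append(
            f"SEQADV {spec.entry_id:<4} {'UNK':>3} {chain_id:1} {author:>4}{icode:1} "
            f"{'UNP':<4} {ref.accession:<9} {'   ':>3} {'':>5} INSERTION"
        )
    return lines


def _augment_cif(doc: gemmi.cif.Document, spec: FixtureSpec, gt: GroundTruth,
                 ref: ReferenceSequence) -> None:
    block = doc.sole_block()
    q = gemmi.cif.quote
    block.set_pair("_entry.id", spec.entry_id)
    block.set_pair("_exptl.method", q(_METHOD_TO_EXPDTA[spec.method]))
    if spec.resolution is not None:
        block.set_pair("_refine.ls_d_res_high", f"{spec.resolution:.2f}")
    if spec.r_work is not None:
        block.set_pair("_refine.ls_R_factor_R_work", f"{spec.r_work:.3f}")
    if spec.r_free is not None:
        block.set_pair("_refine.ls_R_factor_R_free", f"{spec.r_free:.3f}")
    declared_subs = [s for s in gt.substitutions if s[3]]
    if declared_subs or gt.declared_inserted:
        loop = block.init_loop("_struct_ref_seq_dif.", [
            "mon_id", "pdbx_pdb_strand_id", "pdbx_auth_seq_num",
            "pdbx_pdb_ins_code", "db_mon_id", "details"])
        for pos, old, new, _d in declared_subs:
            loop.add_row([_aa.AA_1TO3[new], spec.chain_id,
                          str(pos + spec.chain_offset), ".",
                          _aa.AA_1TO3[old], q("ENGINEERED MUTATION")])
        for chain_id, author, icode in gt.declared_inserted:
            loop.add_row(["UNK", chain_id, str(author), icode or ".",
                          ".", q("INSERTION")])
    if gt.declared_deleted:
        loop = block.init_loop("_pdbx_unobs_or_zero_occ_residues.", [
            "auth_asym_id", "auth_comp_id", "auth_seq_id", "PDB_ins_code"])
        for pos in gt.declared_deleted:
            loop.add_row([spec.chain_id, _aa.AA_1TO3[ref.at(pos)],
                          str(pos + spec.chain_offset), "."])


def make_structure(
    spec: FixtureSpec,
    ref: ReferenceSequence,
    out_dir,
    dialects: tuple[str, ...] = ("pdb",),
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the fixture structure in the requested dialects.

    Returns ``(paths by dialect, ground truth)``.  The header declares
    exactly the edits sampled at ``declared_fraction``; everything else is
    an *undeclared* modification the curation step must discover.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, gt = build_chain_records(spec, ref)
    st = _build_gemmi_structure(spec, records, ref)
    paths: dict[str, Path] = {}
    for dialect in dialects:
        if dialect == "pdb":
            body = st.make_pdb_string()
            header = "\n".join(_pdb_header_lines(spec, gt, ref))
            path = out_dir / f"{spec.entry_id}.pdb"
            path.write_text(header + "\n" + body)
        elif dialect == "mmcif":
            doc = st.make_mmcif_document()
            _augment_cif(doc, spec, gt, ref)
            path = out_dir / f"{spec.entry_id}.cif"
            doc.write_file(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        paths[dialect] = path
    return paths, gt


# ---------------------------------------------------------------------------
# randomized curation fixtures (known-edit recovery)
# ---------------------------------------------------------------------------

def deletion_is_unambiguous(ref_seq: str, lo: int, hi: int) -> bool:
    """True when an unresolved gap over reference positions [lo, hi] cannot
    slide in the optimal alignment: the residue before the gap must differ
    from the last gapped one, and the first gapped one from the residue
    after the gap."""
    left_ok = lo <= 1 or ref_seq[lo - 2] != ref_seq[hi - 1]
    right_ok = hi >= len(ref_seq) or ref_seq[lo - 1] != ref_seq[hi]
    return left_ok and right_ok


def random_fixture_spec(seed: int, ref_length: int = 200) -> FixtureSpec:
    """A randomized structure fixture: random author-number offset (0–100),
    0–8 substitutions, 0–3 deleted ranges, 0–2 insertion runs, with edits
    separated and kept clear of the chain termini."""
    rng = random.Random(f"fixture:{seed}")
    ref_seq = make_reference(FixtureSpec(seed=seed, ref_length=ref_length)).sequence
    n_subs = rng.randint(0, 8)
    n_dels = rng.randint(0, 3)
    n_ins = rng.randint(0, 2)
    margin = 5
    taken: set[int] = set()

    def reserve(width: int, need_unambiguous_gap: bool = False) -> Optional[int]:
        # place a feature of `width` positions with >=3 buffer around it
        for _ in range(200):
            pos = rng.randint(1 + margin, ref_length - margin - width)
            if need_unambiguous_gap and not deletion_is_unambiguous(
                    ref_seq, pos, pos + width - 1):
                continue
            footprint = set(range(pos - 3, pos + width + 3))
            if not footprint & taken:
                taken.update(footprint)
                return pos
        return None

    substitutions = []
    for _ in range(n_subs):
        pos = reserve(1)
        if pos is not None:
            substitutions.append((pos, ""))
    deleted = []
    for _ in range(n_dels):
        width = rng.randint(1, 6)
        pos = reserve(width, need_unambiguous_gap=True)
        if pos is not None:
            deleted.append((pos, pos + width - 1))
    inserted = []
    for _ in range(n_ins):
        width = rng.randint(1, 3)
        pos = reserve(width)
        if pos is not None:
            inserted.append((pos, width))
    return FixtureSpec(
        seed=seed,
        ref_length=ref_length,
        entry_id=f"R{seed % 1000:03d}",
        chain_offset=rng.randint(0, 100),
        substitutions=sorted(substitutions),
        deleted_ranges=sorted(deleted),
        inserted_runs=sorted(inserted),
        declared_fraction=rng.random(),
    )


# ---------------------------------------------------------------------------
# ortholog alignments
# ---------------------------------------------------------------------------

DEFAULT_ORGANISMS = ("chimpanzee", "macaque", "mouse", "rat", "dog",
                     "bovine", "chicken", "zebrafish", "frog")


def default_msa_members(identities=(0.99, 0.98, 0.92, 0.92, 0.9,
                                    0.88, 0.8, 0.65, 0.6)) -> list[MsaMemberSpec]:
    """A nine-ortholog vertebrate panel spanning near-identical primates to
    distant fish/amphibian, emulating the ten-organism study design."""
    return [
        MsaMemberSpec(org, f"ORT{i + 1:05d}", ident, reviewed=(i % 2 == 0))
        for i, (org, ident) in enumerate(zip(DEFAULT_ORGANISMS, identities))
    ]


def make_alignment(spec: FixtureSpec, ref: ReferenceSequence, path) -> None:
    """Write an aligned FASTA of the human reference plus orthologs with
    controlled per-member identity (within ±0.02 of target) and optional
    gap ranges.  Columns equal reference length (human row ungapped)."""
    rng = random.Random(f"msa:{spec.seed}")
    members = spec.msa_members or default_msa_members()
    L = len(ref)
    rows = [(f"{ref.accession} organism=human"
             f"{' reviewed=yes' if ref.reviewed else ''}", ref.sequence)]
    for m in members:
        if not (0.0 <= m.identity_target <= 1.0):
            raise FixtureSpecError(f"identity target {m.identity_target} outside [0,1]")
        seq = list(ref.sequence)
        gap_cols = set()
        for lo, hi in m.gap_ranges:
            gap_cols.update(range(lo, hi + 1))
        nongap = [i for i in range(1, L + 1) if i not in gap_cols]
        k = round((1.0 - m.identity_target) * len(nongap))
        for pos in rng.sample(nongap, k):
            old = seq[pos - 1]
            seq[pos - 1] = rng.choice([a for a in AA20 if a != old])
        for pos in gap_cols:
            seq[pos - 1] = "-"
        header = (f"{m.accession} organism={m.organism}"
                  f"{' reviewed=yes' if m.reviewed else ''}")
        rows.append((header, "".join(seq)))
    with open(path, "w") as fh:
        for header, seq in rows:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# variant tables & ligand dictionaries
# ---------------------------------------------------------------------------

EFFECT_CYCLE = ("activating", "inactivating", "neutral", "unknown")


def make_variant_table(variants: list[str], path, malformed: list[str] = (),
                       ptm_rows: list[tuple[str, str]] = ()) -> None:
    """Variant TSV with effects cycling through the annotation classes.

    ``malformed`` rows are written verbatim (they must be rejected by the
    reader); ``ptm_rows`` are (raw, detail) posttranslational entries.
    """
    with open(path, "w") as fh:
        fh.write("raw\teffect\tsource\tdetail\tptm\n")
        for i, raw in enumerate(variants):
            effect = EFFECT_CYCLE[i % len(EFFECT_CYCLE)]
            fh.write(f"{raw}\t{effect}\tfixture\t\t0\n")
        for raw in malformed:
            fh.write(f"{raw}\tunknown\tfixture\tmalformed row\t0\n")
        for raw, detail in ptm_rows:
            fh.write(f"{raw}\tneutral\tfixture\t{detail}\t1\n")


def make_ligand_dict(entries: dict[str, str], path) -> None:
    """Ligand classification TSV ``comp_id<TAB>category<TAB>usual_name``."""
    with open(path, "w") as fh:
        fh.write("# comp_id\tcategory\tusual_name\n")
        for comp, cat in sorted(entries.items()):
            fh.write(f"{comp}\t{cat}\t{comp.lower()}\n")


# ---------------------------------------------------------------------------
# contact-analysis scenes
# ---------------------------------------------------------------------------

_FRAGMENTS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    # local coordinates; CA at origin, fragments roughly bond-length spaced
    "LYS": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("CG", "C", (0.0, -2.6, 1.0)),
            ("CD", "C", (0.0, -3.9, 0.4)), ("CE", "C", (0.0, -5.0, 1.4)),
            ("NZ", "N", (0.0, -6.3, 0.8))],
    "GLU": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("CG", "C", (0.0, -2.7, 0.9)),
            ("CD", "C", (0.0, -4.0, 0.3)), ("OE1", "O", (0.0, -5.0, 1.0)),
            ("OE2", "O", (0.0, -4.2, -0.95))],
    "ARG": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("CG", "C", (0.0, -2.7, 0.9)),
            ("CD", "C", (0.0, -4.0, 0.3)), ("NE", "N", (0.0, -5.2, 1.1)),
            ("CZ", "C", (0.0, -6.5, 0.7)), ("NH1", "N", (0.0, -7.5, 1.5)),
            ("NH2", "N", (0.0, -6.8, -0.6))],
    "SER": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("OG", "O", (0.0, -2.4, 1.1))],
    "LEU": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("CG", "C", (0.0, -2.8, 0.7)),
            ("CD1", "C", (1.2, -3.7, 0.4)), ("CD2", "C", (-1.3, -3.6, 0.5))],
    "ASN": [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
            ("CB", "C", (0.0, -1.5, 0.0)), ("CG", "C", (0.0, -2.7, 0.9)),
            ("OD1", "O", (0.0, -3.9, 0.5)), ("ND2", "N", (0.0, -2.5, 2.2))],
}


def _phe_fragment() -> list[tuple[str, str, tuple[float, float, float]]]:
    atoms = [("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
             ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
             ("CB", "C", (0.0, -1.5, 0.0))]
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    cx, cy = 0.0, -3.9
    for j, name in enumerate(ring_names):
        ang = math.radians(60.0 * j + 90.0)
        atoms.append((name, "C", (cx + 1.39 * math.cos(ang),
                                  cy + 1.39 * math.sin(ang), 0.0)))
    return atoms


_FRAGMENTS["PHE"] = _phe_fragment()
_FRAGMENTS["HIS"] = [
    ("N", "N", (-1.4, 0.4, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.4, 0.4, 0.0)), ("O", "O", (2.3, -0.3, 0.0)),
    ("CB", "C", (0.0, -1.5, 0.0)),
    ("CG", "C", (0.0, -2.9, -0.2)), ("ND1", "N", (1.1, -3.7, -0.2)),
    ("CD2", "C", (-1.05, -3.8, -0.2)), ("CE1", "C", (0.65, -5.0, -0.2)),
    ("NE2", "N", (-0.7, -5.1, -0.2)),
]


def _random_rotation(rng: random.Random) -> np.ndarray:
    m = np.array([[rng.gauss(0, 1) for _ in range(3)] for _ in range(3)])
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_contact_scene(seed: int, n_residues: int = 14,
                       box: float = 16.0) -> StructureModel:
    """A random scene of chemically typed residue fragments (~100 heavy
    atoms) for exercising contact detection against a brute-force oracle.

    Residues are split across two chains so inter-chain behaviour is
    exercised too.
    """
    rng = random.Random(f"scene:{seed}")
    names = list(_FRAGMENTS)
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    for i in range(n_residues):
        res3 = rng.choice(names)
        rot = _random_rotation(rng)
        center = np.array([rng.uniform(0, box) for _ in range(3)])
        chain_id = "A" if i < n_residues * 2 // 3 else "B"
        atoms = [
            Atom(name=nm, element=el,
                 coords=center + rot @ np.array(xyz),
                 occupancy=1.0, b_factor=20.0)
            for nm, el, xyz in _FRAGMENTS[res3]
        ]
        chains[chain_id].append(
            Residue(chain_id=chain_id, author_seq=len(chains[chain_id]) + 1,
                    icode="", res_name=res3,
                    one_letter=_aa.three_to_one(res3), atoms=atoms)
        )
    header = StructureHeader(entry_id=f"SC{seed % 100:02d}", method=Method.XRAY,
                             resolution=1.5)
    model = StructureModel(
        header=header,
        chains=[ChainModel("A", chains["A"]), ChainModel("B", chains["B"])],
        ligands=[],
    )
    return model


# ---------------------------------------------------------------------------
# demo workspace (end-to-end)
# ---------------------------------------------------------------------------

def make_demo_workspace(root, seed: int = 0) -> dict:
    """A complete three-structure workspace: structures, reference FASTA,
    ortholog MSA, variant table, ligand dictionary and remark table.

    FX1A is a high-quality drug-bound complex covering the full reference;
    FX2B is a lower-resolution apo structure with an unresolved loop; FX3C
    carries eleven engineered mutations and must be filtered out.  Returns
    the ground truth needed to verify an end-to-end run.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    struct_dir = root / "structures"
    struct_dir.mkdir(exist_ok=True)
    base = FixtureSpec(seed=seed, ref_length=120)
    ref = make_reference(base, accession="REF00001", gene="DEMO1")
    write_reference_fasta(ref, root / "reference.fasta")

    spec1 = FixtureSpec(
        seed=seed, ref_length=120, entry_id="FX1A",
        resolution=1.2, r_work=0.15, r_free=0.18,
        ligands=[LigandFixture("STI", (8.0, 0.0, 40.0))],
        n_waters=3,
        partner_chain=PartnerChainFixture("B", 40, (15.0, 0.0, 0.0)),
    )
    _, gt1 = make_structure(spec1, ref, struct_dir, ("pdb",))

    del_lo = next(lo for lo in range(55, 90)
                  if deletion_is_unambiguous(ref.sequence, lo, lo + 4))
    spec2 = FixtureSpec(
        seed=seed + 1, ref_length=120, entry_id="FX2B",
        chain_span=(11, 110), chain_offset=30,
        deleted_ranges=[(del_lo, del_lo + 4)],
        resolution=2.5, r_work=0.21, r_free=0.26,
        declared_fraction=1.0,
    )
    _, gt2 = make_structure(spec2, ref, struct_dir, ("pdb",))

    rng = random.Random(f"demo3:{seed}")
    sub_positions = sorted(rng.sample(range(8, 113, 4), 11))
    spec3 = FixtureSpec(
        seed=seed + 2, ref_length=120, entry_id="FX3C",
        substitutions=[(p, "") for p in sub_positions],
        resolution=1.9, declared_fraction=0.5,
    )
    _, gt3 = make_structure(spec3, ref, struct_dir, ("pdb",))

    make_alignment(FixtureSpec(seed=seed, ref_length=120), ref, root / "orthologs.afa")
    make_variant_table(
        [f"{ref.at(60)}60{'E' if ref.at(60) != 'E' else 'K'}",
         f"{ref.at(30)}30*",
         f"{ref.at(del_lo + 2)}{del_lo + 2}_{ref.at(del_lo + 4)}{del_lo + 4}del",
         f"{ref.at(90)}90fs"],
        root / "variants.tsv",
        malformed=["?bogus?"],
        ptm_rows=[(f"{ref.at(45)}45{'D' if ref.at(45) != 'D' else 'N'}", "phosphosite")],
    )
    make_ligand_dict({"STI": "approved_drug", "GOL": "buffer", "NAG": "sugar"},
                     root / "ligands.tsv")
    with open(root / "remarks.tsv", "w") as fh:
        fh.write("entry_id\tdomain_tags\tstate_tag\tnotes\n")
        fh.write("FX1A\tkinase\tactive\tdrug-bound complex\n")
        fh.write("FX2B\tkinase\tinactive\tapo form\n")
        fh.write("FX3C\tkinase\tunknown\theavily engineered\n")
    return {
        "reference": ref,
        "ground_truth": {"FX1A": gt1.to_dict(), "FX2B": gt2.to_dict(), "FX3C": gt3.to_dict()},
        "expected_ranking": ["FX1A", "FX2B"],
        "expected_filtered": ["FX3C"],
        "fx2b_deleted_range": (del_lo, del_lo + 4),
        "paths": {
            "structures_dir": str(struct_dir),
            "reference_fasta": str(root / "reference.fasta"),
            "msa": str(root / "orthologs.afa"),
            "variant_table": str(root / "variants.tsv"),
            "ligand_dict": str(root / "ligands.tsv"),
            "remark_table": str(root / "remarks.tsv"),
        },
    }
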