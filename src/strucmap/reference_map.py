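"""Map structure chains onto a reference (UniProt-style) sequence.

Each chain is aligned semi-globally to its reference sequence, residues are
renumbered into 1-based reference positions, and discrepancies — mutated,
missing, and inserted residues, including those undeclared in the file
header — are reported.  Chains and structures are then filtered: a chain is
kept only if strictly fewer than 30% of the reference positions it spans are
unresolved, and a structure is dropped when its chains carry more than ten
mutations in total (with a per-entry override list for the rare gene whose
only available structure exceeds that, the GNA11 situation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .io_structures import ChainModel, StructureHeader, StructureModel, ResidueKey


class AlignmentError(ValueError):
    """No confident chain-to-reference mapping could be established."""


@dataclass(frozen=True)
class ReferenceSequence:
    accession: str
    sequence: str  # 1-letter, 1-based positions
    gene: str = ""
    reviewed: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def at(self, pos: int) -> str:
        """Residue at a 1-based reference position."""
        return self.sequence[pos - 1]


def read_reference_fasta(path) -> list[ReferenceSequence]:
    """Read reference sequences from FASTA.

    The accession is the header token up to the first whitespace; pipe-
    delimited UniProt-style headers (``sp|P01112|RASH_HUMAN``) use the field
    after the database tag.  A ``gene=`` token in the description is honoured.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        reviewed = False
        if "|" in ident:
            fields = ident.split("|")
            if len(fields) >= 2:
                reviewed = fields[0] == "sp"
                ident = fields[1]
        gene = ""
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[5:]
            if tok == "reviewed=yes":
                reviewed = True
        out.append(ReferenceSequence(accession=ident, gene=gene,
                                     sequence=str(rec.seq).upper(),
                                     reviewed=reviewed))
    return out


@dataclass
class ChainAlignment:
    chain_id: str
    ref_accession: str
    #: (author residue key or None, reference position or None) per column
    aligned_pairs: list[tuple[Optional[ResidueKey], Optional[int]]]
    identity: float
    ref_span: tuple[int, int]
    score: float
    ref_length: int

    @property
    def ref_span_length(self) -> int:
        return self.ref_span[1] - self.ref_span[0] + 1


@dataclass
class MutatedResidue:
    ref_pos: int
    ref_aa: str
    chain_aa: str
    author_key: ResidueKey
    declared: bool = False


@dataclass
class MissingResidue:
    ref_pos: int
    declared: bool = False


@dataclass
class InsertedResidue:
    author_key: ResidueKey
    label: str  # ordinal tag like "412+1"
    declared: bool = False


@dataclass
class Discrepancies:
    mutated: list[MutatedResidue] = field(default_factory=list)
    missing: list[MissingResidue] = field(default_factory=list)
    inserted: list[InsertedResidue] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "mutated": [(m.ref_pos, m.ref_aa, m.chain_aa, m.declared) for m in self.mutated],
            "missing": [(m.ref_pos, m.declared) for m in self.missing],
            "inserted": [(list(i.author_key), i.label, i.declared) for i in self.inserted],
        }


@dataclass
class FilterConfig:
    max_missing_fraction: float = 0.30
    max_mutations: int = 10
    allow_override: frozenset[str] = frozenset()
    min_identity: float = 0.30

    def __post_init__(self) -> None:
        if not (0 < self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if self.max_mutations < 0:
            raise ValueError("max_mutations must be >= 0")
        self.allow_override = frozenset(self.allow_override)


@dataclass
class RenumberedChain:
    chain_id: str
    ref_accession: str
    ref_length: int
    #: author residue key -> reference position (None for insertions)
    mapping: dict[ResidueKey, Optional[int]]
    #: author residue key -> ordinal tag for insertions ("<prev_ref_pos>+k")
    insertion_labels: dict[ResidueKey, str]
    discrepancies: Discrepancies
    ref_span: tuple[int, int]
    missing_fraction: float
    kept: bool

    def resolved_positions(self) -> set[int]:
        return {p for p in self.mapping.values() if p is not None}

    def position_of(self, key: ResidueKey) -> Optional[int]:
        return self.mapping.get(key)

    def author_key_of(self, ref_pos: int) -> Optional[ResidueKey]:
        for k, p in self.mapping.items():
            if p == ref_pos:
                return k
        return None

    @property
    def coverage_of_span(self) -> float:
        return 1.0 - self.missing_fraction

    def ref_span_len_resolved(self) -> int:
        """Number of reference positions in the span with a resolved residue."""
        lo, hi = self.ref_span
        return len({p for p in self.mapping.values() if p is not None and lo <= p <= hi})


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    # free end gaps in the query row, i.e. reference overhangs beyond the
    # chain carry no penalty (semi-global alignment)
    aligner.end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def align_chain_to_reference(
    chain: ChainModel,
    ref: ReferenceSequence,
    min_identity: float = 0.30,
) -> ChainAlignment:
    """Semi-global alignment of a chain's observed sequence to the reference.

    Uses affine-gap dynamic programming with BLOSUM62 (open 11, extend 1);
    reference overhangs are free.  Raises :class:`AlignmentError` when the
    identity over aligned columns falls below ``min_identity``.
    """
    if len(chain) == 0:
        raise ValueError("chain has no residues")
    seq = chain.seq_observed
    aln = _ALIGNER.align(ref.sequence, seq)[0]
    ref_idx, chain_idx = aln.indices  # -1 at gaps

    pairs: list[tuple[Optional[ResidueKey], Optional[int]]] = []
    matches = 0
    aligned_cols = 0
    first_ref = last_ref = None
    keys = [r.key for r in chain.residues]
    for ri, ci in zip(ref_idx, chain_idx):
        ref_pos = int(ri) + 1 if ri >= 0 else None
        key = keys[int(ci)] if ci >= 0 else None
        if ref_pos is not None and key is not None:
            aligned_cols += 1
            if ref.sequence[ref_pos - 1] == seq[int(ci)]:
                matches += 1
            if first_ref is None:
                first_ref = ref_pos
            last_ref = ref_pos
        if key is None and ref_pos is not None and (first_ref is None or last_ref is None):
            # reference overhang before the chain starts: not part of span
            continue
        pairs.append((key, ref_pos))

    if aligned_cols == 0 or first_ref is None:
        raise AlignmentError(
            f"chain {chain.chain_id}: no aligned columns against {ref.accession}"
        )
    identity = matches / aligned_cols
    if identity < min_identity:
        raise AlignmentError(
            f"chain {chain.chain_id}: identity {identity:.2f} to {ref.accession} "
            f"below confidence floor {min_identity:.2f}"
        )
    # trim trailing reference overhang columns (after the last aligned residue)
    while pairs and pairs[-1][0] is None and (pairs[-1][1] is None or pairs[-1][1] > last_ref):
        pairs.pop()
    return ChainAlignment(
        chain_id=chain.chain_id,
        ref_accession=ref.accession,
        aligned_pairs=pairs,
        identity=identity,
        ref_span=(first_ref, last_ref),
        score=float(aln.score),
        ref_length=len(ref),
    )


def detect_discrepancies(
    aln: ChainAlignment,
    chain: ChainModel,
    ref: ReferenceSequence,
    header: Optional[StructureHeader] = None,
) -> Discrepancies:
    """Report mutated, missing and inserted residues relative to the reference.

    Mutated residues are mismatch columns; missing residues are reference
    positions inside the aligned span with no structure residue; insertions
    are structure residues aligned to no reference position.  Each record is
    flagged declared/undeclared against the file header, so modifications
    unmentioned in the original annotations are identifiable.
    """
    res_by_key = {r.key: r for r in chain.residues}
    d = Discrepancies()
    lo, hi = aln.ref_span
    # local author-number offset, for inferring what author number a missing
    # residue would have carried (used only for the declared/undeclared flag)
    offsets: dict[int, int] = {}
    prev_ref: Optional[int] = None
    ins_count = 0
    for key, ref_pos in aln.aligned_pairs:
        if key is not None and ref_pos is not None:
            res = res_by_key[key]
            offsets[ref_pos] = key[1] - ref_pos
            if ref.at(ref_pos) != res.one_letter:
                declared = bool(header and header.declares_mutation_at(*key))
                d.mutated.append(
                    MutatedResidue(ref_pos, ref.at(ref_pos), res.one_letter, key, declared)
                )
            prev_ref = ref_pos
            ins_count = 0
        elif key is None and ref_pos is not None and lo <= ref_pos <= hi:
            d.missing.append(MissingResidue(ref_pos))
        elif key is not None and ref_pos is None:
            ins_count += 1
            anchor = prev_ref if prev_ref is not None else lo - 1
            declared = bool(header and header.declares_mutation_at(*key))
            d.inserted.append(InsertedResidue(key, f"{anchor}+{ins_count}", declared))
    if header is not None:
        # a missing residue is declared if the author number it would have had
        # (nearest-anchor offset) appears in the header's missing list
        declared_missing = {(k[1], k[2]) for k in header.declared_missing
                            if k[0] == chain.chain_id}
        anchors = sorted(offsets)
        for m in d.missing:
            if not anchors:
                break
            nearest = min(anchors, key=lambda a: abs(a - m.ref_pos))
            expected_author = m.ref_pos + offsets[nearest]
            m.declared = (expected_author, "") in declared_missing
    return d


def renumber_chain(
    chain: ChainModel,
    aln: ChainAlignment,
    cfg: FilterConfig = FilterConfig(),
    header: Optional[StructureHeader] = None,
    ref: Optional[ReferenceSequence] = None,
) -> RenumberedChain:
    """Assign every resolved residue its reference position.

    Insertions relative to the reference get no position and are labelled
    with an ordinal tag ``<previous_reference_position>+k``.  The chain is
    kept only when its missing fraction over the spanned reference region is
    strictly below ``cfg.max_missing_fraction``.
    """
    mapping: dict[ResidueKey, Optional[int]] = {}
    labels: dict[ResidueKey, str] = {}
    discrepancies = (
        detect_discrepancies(aln, chain, ref, header) if ref is not None else Discrepancies()
    )
    ins_by_key = {i.author_key: i.label for i in discrepancies.inserted}
    prev_ref: Optional[int] = None
    ins_count = 0
    for key, ref_pos in aln.aligned_pairs:
        if key is None:
            continue
        mapping[key] = ref_pos
        if ref_pos is None:
            ins_count += 1
            anchor = prev_ref if prev_ref is not None else aln.ref_span[0] - 1
            labels[key] = ins_by_key.get(key, f"{anchor}+{ins_count}")
        else:
            prev_ref = ref_pos
            ins_count = 0
    span_len = aln.ref_span_length
    mapped_positions = {p for p in mapping.values() if p is not None}
    n_missing = span_len - len(
        {p for p in mapped_positions if aln.ref_span[0] <= p <= aln.ref_span[1]}
    )
    missing_fraction = n_missing / span_len if span_len else 0.0
    return RenumberedChain(
        chain_id=chain.chain_id,
        ref_accession=aln.ref_accession,
        ref_length=aln.ref_length,
        mapping=mapping,
        insertion_labels=labels,
        discrepancies=discrepancies,
        ref_span=aln.ref_span,
        missing_fraction=missing_fraction,
        kept=missing_fraction < cfg.max_missing_fraction,
    )


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)
    override_used: bool = False
    n_mutations: int = 0


def apply_structure_filters(
    model: StructureModel,
    renumbered: list[RenumberedChain],
    cfg: FilterConfig = FilterConfig(),
) -> FilterDecision:
    """Structure-level keep/drop decision with explicit reasons.

    Drops a structure when the total mutation count across its mapped chains
    is strictly greater than ``cfg.max_mutations`` — unless its entry id is
    in ``cfg.allow_override`` — and when no chain survives the missing-
    residue filter.
    """
    reasons: list[str] = []
    drop = False
    override_used = False
    n_mut = sum(len(rc.discrepancies.mutated) for rc in renumbered)
    if n_mut > cfg.max_mutations:
        if model.header.entry_id in cfg.allow_override:
            override_used = True
            reasons.append(
                f"mutation-count {n_mut} > {cfg.max_mutations} overridden for "
                f"{model.header.entry_id}"
            )
        else:
            drop = True
            reasons.append(f"mutation-count: {n_mut} mutations > {cfg.max_mutations}")
    if renumbered and not any(rc.kept for rc in renumbered):
        drop = True
        reasons.append("no-chain-kept: all chains exceed the missing-residue limit")
    if not renumbered:
        drop = True
        reasons.append("no-mapped-chain: no chain aligned to a reference")
    return FilterDecision(keep=not drop, reasons=reasons,
                          override_used=override_used, n_mutations=n_mut)


def mapping_table(rc: RenumberedChain) -> list[dict]:
    """Rows for the renumbering TSV: chain, author_seq, icode, ref_pos, status."""
    mutated_keys = {m.author_key for m in rc.discrepancies.mutated}
    rows = []
    for key in sorted(rc.mapping, key=lambda k: (k[1], k[2])):
        ref_pos = rc.mapping[key]
        if ref_pos is None:
            status = "inserted"
            shown = rc.insertion_labels.get(key, "")
        else:
            status = "mutated" if key in mutated_keys else "match"
            shown = str(ref_pos)
        rows.append({
            "chain": key[0], "author_seq": key[1], "icode": key[2],
            "ref_pos": shown, "status": status,
        })
    return rows
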