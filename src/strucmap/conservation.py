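"""Ortholog conservation from a precomputed multiple sequence alignment.

The MSA (human protein plus orthologs, typically a ten-organism vertebrate
panel) is consumed as aligned FASTA or Clustal; columns are mapped onto the
human reference numbering and per-position conservation is reported as
identity to the human residue over the non-gap ortholog rows.  Positions
with no non-gap ortholog have *undefined* conservation — an explicit
marker, never 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio import AlignIO

GAP_CHARS = frozenset("-.")


class AlignmentFormatError(ValueError):
    pass


class ReferenceMissingError(ValueError):
    pass


@dataclass
class AlignmentMember:
    organism: str
    accession: str
    reviewed: bool
    aligned_sequence: str

    @property
    def label(self) -> str:
        """Organism label with the reviewed-sequence asterisk convention."""
        return f"{self.organism}*" if self.reviewed else self.organism


@dataclass
class OrthologAlignment:
    members: list[AlignmentMember]
    human_index: int

    def __post_init__(self) -> None:
        lengths = {len(m.aligned_sequence) for m in self.members}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if not (0 <= self.human_index < len(self.members)):
            raise ReferenceMissingError("human member index out of range")

    @property
    def columns(self) -> int:
        return len(self.members[0].aligned_sequence) if self.members else 0

    @property
    def human(self) -> AlignmentMember:
        return self.members[self.human_index]

    @property
    def human_ungapped(self) -> str:
        return "".join(c for c in self.human.aligned_sequence if c not in GAP_CHARS)


def _parse_member(record) -> AlignmentMember:
    """Fixture/UniProt-ish header convention:
    ``>ACC organism=mouse reviewed=yes`` or ``>sp|ACC|NAME_MOUSE``."""
    ident = record.id
    organism = ""
    reviewed = False
    if "|" in ident:
        fields = ident.split("|")
        reviewed = fields[0] == "sp"
        if len(fields) >= 2:
            ident = fields[1]
        if len(fields) >= 3 and "_" in fields[2]:
            organism = fields[2].split("_")[-1].lower()
    for tok in record.description.split():
        if tok.startswith("organism="):
            organism = tok[len("organism="):]
        elif tok == "reviewed=yes":
            reviewed = True
    return AlignmentMember(
        organism=organism or ident,
        accession=ident,
        reviewed=reviewed,
        aligned_sequence=str(record.seq).upper(),
    )


def read_alignment(
    path,
    format: str = "aligned-fasta",
    human_accession: Optional[str] = None,
) -> OrthologAlignment:
    """Read an ortholog MSA (``aligned-fasta`` or ``clustal``).

    The human member is identified by ``human_accession`` when given,
    otherwise by an ``organism=human`` tag (or ``_HUMAN`` suffix) in the
    header.  A ragged alignment or an absent human member is an error.
    """
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format: {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot read {path} as {format}: {exc}") from exc
    members = [_parse_member(rec) for rec in msa]
    human_index = None
    for i, m in enumerate(members):
        if human_accession is not None:
            if m.accession == human_accession:
                human_index = i
                break
        elif m.organism.lower() == "human":
            human_index = i
            break
    if human_index is None:
        raise ReferenceMissingError(
            f"human reference member not found in {path} "
            f"(looked for {'accession ' + human_accession if human_accession else 'organism=human'})"
        )
    return OrthologAlignment(members=members, human_index=human_index)


def column_to_position(aln: OrthologAlignment) -> tuple[dict[int, Optional[int]], dict[int, int]]:
    """Bidirectional map between 1-based alignment columns and 1-based
    reference positions of the human sequence.

    Returns ``(col_to_pos, pos_to_col)``; gap columns of the human row map
    to ``None`` and appear in no reverse entry.
    """
    col_to_pos: dict[int, Optional[int]] = {}
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aln.human.aligned_sequence, start=1):
        if ch in GAP_CHARS:
            col_to_pos[col] = None
        else:
            pos += 1
            col_to_pos[col] = pos
            pos_to_col[pos] = col
    return col_to_pos, pos_to_col


@dataclass
class PositionConservation:
    ref_pos: int
    column: int
    human_aa: str
    n_identical: int
    n_nongap: int
    gap_count: int

    @property
    def identity_fraction(self) -> Optional[float]:
        """Identity to human over non-gap orthologs; None when undefined
        (no non-gap ortholog at this column)."""
        if self.n_nongap == 0:
            return None
        return self.n_identical / self.n_nongap


@dataclass
class ConservationProfile:
    positions: list[PositionConservation]
    member_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    def at(self, ref_pos: int) -> PositionConservation:
        return self.positions[ref_pos - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.positions:
            f = p.identity_fraction
            rows.append({
                "ref_pos": p.ref_pos,
                "human_aa": p.human_aa,
                "identity_fraction": ("NA" if f is None else round(f, 4)),
                "n_nongap": p.n_nongap,
                "gap_count": p.gap_count,
            })
        return pd.DataFrame(rows, columns=["ref_pos", "human_aa", "identity_fraction",
                                           "n_nongap", "gap_count"])

    def write_tsv(self, path) -> None:
        """Profile TSV with a leading annotation row carrying the member
        labels (reviewed sequences marked with an asterisk)."""
        with open(path, "w") as fh:
            if self.member_labels:
                fh.write("# members: " + ", ".join(self.member_labels) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def conservation_profile(aln: OrthologAlignment) -> ConservationProfile:
    """Per-reference-position conservation: identity of non-gap ortholog
    residues to the human residue.  The human row is counted in neither
    numerator nor denominator."""
    col_to_pos, pos_to_col = column_to_position(aln)
    others = [m for i, m in enumerate(aln.members) if i != aln.human_index]
    human_seq = aln.human.aligned_sequence
    positions: list[PositionConservation] = []
    for pos in sorted(pos_to_col):
        col = pos_to_col[pos]
        h = human_seq[col - 1]
        n_ident = n_nongap = gaps = 0
        for m in others:
            ch = m.aligned_sequence[col - 1]
            if ch in GAP_CHARS:
                gaps += 1
            else:
                n_nongap += 1
                if ch == h:
                    n_ident += 1
        positions.append(PositionConservation(pos, col, h, n_ident, n_nongap, gaps))
    return ConservationProfile(
        positions=positions,
        member_labels=[m.label for m in aln.members],
    )
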