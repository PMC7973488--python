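"""Read PDB/mmCIF coordinate files and decompose them into chains, ligands
and peptides, with the header metadata the curation pipeline needs.

Coordinates are parsed with :mod:`gemmi`; header records that gemmi does not
uniformly surface from minimal files (SEQADV, REMARK 465, REMARK 2/3, and the
matching mmCIF categories) are extracted by targeted readers here.
"""

from __future__ import annotations

import enum
import json
import math
import os
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

from . import _aa

ResidueKey = tuple[str, int, str]  # (chain_id, author_seq, icode)


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or is empty."""


class Method(str, enum.Enum):
    XRAY = "xray"
    NEUTRON = "neutron"
    NMR = "nmr"
    FIBER = "fiber"
    CRYOEM = "cryoem"
    MODEL = "model"
    UNKNOWN = "unknown"


_METHOD_STRINGS = {
    "X-RAY DIFFRACTION": Method.XRAY,
    "NEUTRON DIFFRACTION": Method.NEUTRON,
    "SOLUTION NMR": Method.NMR,
    "SOLID-STATE NMR": Method.NMR,
    "FIBER DIFFRACTION": Method.FIBER,
    "ELECTRON MICROSCOPY": Method.CRYOEM,
    "ELECTRON CRYSTALLOGRAPHY": Method.CRYOEM,
    "THEORETICAL MODEL": Method.MODEL,
}


def method_from_string(s: str) -> Method:
    return _METHOD_STRINGS.get(s.strip().upper(), Method.UNKNOWN)


class LigandCategory(str, enum.Enum):
    APPROVED_DRUG = "approved_drug"
    INVESTIGATIONAL = "investigational"
    SUGAR = "sugar"
    ION = "ion"
    WATER = "water"
    BUFFER = "buffer"
    OTHER = "other"


#: categories hidden by default (irrelevant for display, like buffer molecules)
HIDDEN_CATEGORIES = frozenset({LigandCategory.WATER, LigandCategory.BUFFER})

WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coords"] = [float(x) for x in self.coords]
        return d


@dataclass
class Residue:
    chain_id: str
    author_seq: int
    icode: str
    res_name: str
    one_letter: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.author_seq, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "author_seq": self.author_seq,
            "icode": self.icode,
            "res_name": self.res_name,
            "one_letter": self.one_letter,
            "atoms": [a.to_dict() for a in self.atoms],
        }


class EntityKind(str, enum.Enum):
    PROTEIN = "protein"
    PEPTIDE = "peptide"
    OTHER = "other"


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue]
    entity_kind: EntityKind = EntityKind.PROTEIN

    @property
    def seq_observed(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_key(self, author_seq: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.author_seq == author_seq and r.icode == icode:
                return r
        return None

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "entity_kind": self.entity_kind.value,
            "seq_observed": self.seq_observed,
            "residues": [r.to_dict() for r in self.residues],
        }


@dataclass
class LigandEntry:
    comp_id: str
    chain_id: str
    instance_id: str  # author_seq + icode, e.g. "201"
    category: LigandCategory = LigandCategory.OTHER
    display: str = "shown"  # shown | hidden
    atoms: list[Atom] = field(default_factory=list)
    author_seq: int = 0
    icode: str = ""

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.author_seq, self.icode)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def to_dict(self) -> dict:
        return {
            "comp_id": self.comp_id,
            "chain_id": self.chain_id,
            "instance_id": self.instance_id,
            "category": self.category.value,
            "display": self.display,
            "atoms": [a.to_dict() for a in self.atoms],
        }


@dataclass
class DeclaredDifference:
    """One header-declared sequence difference (e.g. an engineered mutation)."""
    chain_id: str
    author_seq: int
    icode: str = ""
    res_name: str = ""
    ref_res_name: str = ""
    comment: str = ""


@dataclass
class StructureHeader:
    entry_id: str = ""
    method: Method = Method.UNKNOWN
    resolution: Optional[float] = None
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    declared_mutations: list[DeclaredDifference] = field(default_factory=list)
    declared_missing: list[ResidueKey] = field(default_factory=list)
    assembly_note: str = ""

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")
        if self.r_free is not None and self.r_free < 0:
            raise ValueError("r_free must be non-negative when present")

    def declares_mutation_at(self, chain_id: str, author_seq: int, icode: str = "") -> bool:
        return any(
            d.chain_id == chain_id and d.author_seq == author_seq and d.icode == icode
            for d in self.declared_mutations
        )

    def declares_missing(self, chain_id: str, author_seq: int, icode: str = "") -> bool:
        return (chain_id, author_seq, icode) in set(self.declared_missing)

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "method": self.method.value,
            "resolution": self.resolution,
            "r_work": self.r_work,
            "r_free": self.r_free,
            "declared_mutations": [asdict(d) for d in self.declared_mutations],
            "declared_missing": [list(k) for k in self.declared_missing],
            "assembly_note": self.assembly_note,
        }


@dataclass
class StructureModel:
    header: StructureHeader
    chains: list[ChainModel]
    ligands: list[LigandEntry]

    def chain(self, chain_id: str) -> Optional[ChainModel]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues) + sum(
            len(l.atoms) for l in self.ligands
        )

    def find_entity(self, key: ResidueKey):
        """Residue or LigandEntry at an author key, or None."""
        chain_id, seq, icode = key
        c = self.chain(chain_id)
        if c is not None:
            r = c.residue_by_key(seq, icode)
            if r is not None:
                return r
        for lig in self.ligands:
            if lig.key == key:
                return lig
        return None

    def to_dict(self) -> dict:
        return {
            "header": self.header.to_dict(),
            "chains": [c.to_dict() for c in self.chains],
            "ligands": [l.to_dict() for l in self.ligands],
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# header extraction
# ---------------------------------------------------------------------------

_RES_RE = re.compile(r"RESOLUTION\.\s+([\d.]+)\s+ANGSTROM", re.I)
_RWORK_RE = re.compile(r"R VALUE\s+\(WORKING SET\)\s*:\s*([\d.]+)")
_RFREE_RE = re.compile(r"FREE R VALUE\s+:\s*([\d.]+)")


def _parse_pdb_header(text: str) -> StructureHeader:
    entry_id = ""
    method = Method.UNKNOWN
    resolution = r_work = r_free = None
    declared_mut: list[DeclaredDifference] = []
    declared_missing: list[ResidueKey] = []
    in_465 = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "HEADER":
            entry_id = line[62:66].strip()
        elif rec == "EXPDTA":
            method = method_from_string(line[10:].split(";")[0])
        elif rec == "REMARK":
            try:
                num = int(line[7:10])
            except ValueError:
                continue
            if num == 2:
                m = _RES_RE.search(line)
                if m:
                    resolution = float(m.group(1))
            elif num == 3:
                m = _RWORK_RE.search(line)
                if m:
                    r_work = float(m.group(1))
                m = _RFREE_RE.search(line)
                if m:
                    r_free = float(m.group(1))
            elif num == 465:
                body = line[10:].rstrip()
                toks = body.split()
                if toks[:4] == ["M", "RES", "C", "SSSEQI"]:
                    in_465 = True
                    continue
                if in_465 and len(toks) >= 3 and toks[0].upper() != "MISSING":
                    # tokens: [model] resName chain seqIcode
                    if len(toks) == 4:
                        toks = toks[1:]
                    res_name, chain_id, seqi = toks[0], toks[1], toks[2]
                    m2 = re.match(r"(-?\d+)([A-Za-z]?)$", seqi)
                    if m2:
                        declared_missing.append(
                            (chain_id, int(m2.group(1)), m2.group(2))
                        )
        elif rec == "SEQADV":
            # PDB v3.3 fixed columns
            res_name = line[12:15].strip()
            chain_id = line[16:17].strip()
            try:
                author_seq = int(line[18:22])
            except ValueError:
                continue
            icode = line[22:23].strip()
            ref_res = line[39:42].strip()
            comment = line[49:].strip()
            declared_mut.append(
                DeclaredDifference(chain_id, author_seq, icode, res_name, ref_res, comment)
            )
    return StructureHeader(
        entry_id=entry_id,
        method=method,
        resolution=resolution,
        r_work=r_work,
        r_free=r_free,
        declared_mutations=declared_mut,
        declared_missing=declared_missing,
    )


def _cif_float(block, tag: str) -> Optional[float]:
    v = block.find_value(tag)
    if v in (None, "?", "."):
        return None
    try:
        return float(v)
    except ValueError:
        return None


def _parse_cif_header(path: str) -> StructureHeader:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    entry_id = block.find_value("_entry.id") or block.name
    method_s = block.find_value("_exptl.method") or ""
    method = method_from_string(method_s.strip("'\""))
    resolution = _cif_float(block, "_refine.ls_d_res_high")
    r_work = _cif_float(block, "_refine.ls_R_factor_R_work")
    r_free = _cif_float(block, "_refine.ls_R_factor_R_free")

    declared_mut: list[DeclaredDifference] = []
    tab = block.find(
        "_struct_ref_seq_dif.",
        ["mon_id", "pdbx_pdb_strand_id", "pdbx_auth_seq_num",
         "pdbx_pdb_ins_code", "db_mon_id", "details"],
    )
    for row in tab:
        icode = row[3]
        icode = "" if icode in ("?", ".") else icode
        try:
            seq = int(row[2])
        except ValueError:
            continue
        declared_mut.append(
            DeclaredDifference(row[1], seq, icode, row[0],
                               "" if row[4] in ("?", ".") else row[4],
                               gemmi.cif.as_string(row[5])))

    declared_missing: list[ResidueKey] = []
    tab = block.find(
        "_pdbx_unobs_or_zero_occ_residues.",
        ["auth_asym_id", "auth_comp_id", "auth_seq_id", "PDB_ins_code"],
    )
    for row in tab:
        icode = row[3]
        icode = "" if icode in ("?", ".") else icode
        try:
            seq = int(row[2])
        except ValueError:
            continue
        declared_missing.append((row[0], seq, icode))

    return StructureHeader(
        entry_id=entry_id,
        method=method,
        resolution=resolution,
        r_work=r_work,
        r_free=r_free,
        declared_mutations=declared_mut,
        declared_missing=declared_missing,
    )


# ---------------------------------------------------------------------------
# coordinate parsing
# ---------------------------------------------------------------------------

def _sniff_dialect(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    if ext in (".pdb", ".ent"):
        return "pdb"
    with open(path) as fh:
        head = fh.read(2048)
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, tie broken by first altloc
    label alphabetically (blank altloc sorts first)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occ, a.altloc or " "))
        out.append(best)
    return out


def read_structure(path: str | os.PathLike, dialect: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a decomposed :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first altloc label); only the first model of multi-model files is
    used.  Polymer residues (standard amino acids plus common nonstandard
    ones such as MSE) go to chains; everything else becomes a ligand entry.
    """
    path = str(path)
    if not os.path.exists(path):
        raise StructureParseError(f"no such file: {path}")
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect: {dialect!r}")

    fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {dialect}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"empty structure (no models): {path}")

    if dialect == "pdb":
        with open(path) as fh:
            header = _parse_pdb_header(fh.read())
    else:
        header = _parse_cif_header(path)
    if not header.entry_id:
        header.entry_id = st.name or os.path.splitext(os.path.basename(path))[0]

    model = st[0]  # first model only
    chains: list[ChainModel] = []
    ligands: list[LigandEntry] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            icode = res.seqid.icode.strip()
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                    is_hetero=(res.het_flag == "H"),
                )
                for a in _resolve_altlocs(res)
            ]
            if _aa.is_polymer_residue(res.name):
                residues.append(
                    Residue(
                        chain_id=ch.name,
                        author_seq=res.seqid.num,
                        icode=icode,
                        res_name=res.name,
                        one_letter=_aa.three_to_one(res.name),
                        atoms=atoms,
                    )
                )
            else:
                comp = res.name.upper()
                ligands.append(
                    LigandEntry(
                        comp_id=comp,
                        chain_id=ch.name,
                        instance_id=f"{res.seqid.num}{icode}",
                        category=(LigandCategory.WATER if comp in WATER_NAMES
                                  else LigandCategory.OTHER),
                        display=("hidden" if comp in WATER_NAMES else "shown"),
                        atoms=atoms,
                        author_seq=res.seqid.num,
                        icode=icode,
                    )
                )
        if residues:
            residues.sort(key=lambda r: (r.author_seq, r.icode))
            chains.append(ChainModel(chain_id=ch.name, residues=residues))

    if not chains and not ligands:
        raise StructureParseError(f"empty coordinate section: {path}")
    if not chains:
        raise StructureParseError(f"no protein chain in {path}")
    return StructureModel(header=header, chains=chains, ligands=ligands)


# ---------------------------------------------------------------------------
# entity classification
# ---------------------------------------------------------------------------

def read_ligand_dict(path: str | os.PathLike) -> dict[str, LigandCategory]:
    """Ligand classification TSV: ``comp_id<TAB>category<TAB>usual_name``."""
    table: dict[str, LigandCategory] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            comp, cat = parts[0].strip().upper(), parts[1].strip().lower()
            try:
                table[comp] = LigandCategory(cat)
            except ValueError:
                table[comp] = LigandCategory.OTHER
    return table


def classify_entities(
    model: StructureModel,
    ligand_dict: Optional[dict[str, LigandCategory]] = None,
    peptide_max_len: int = 30,
    mapped_chain_ids: Iterable[str] = (),
) -> StructureModel:
    """Label short unmapped chains as peptides and assign ligand categories.

    Classification is total: unknown ligand codes fall back to ``other``;
    water and buffer entries default to hidden display.
    """
    ligand_dict = ligand_dict or {}
    mapped = set(mapped_chain_ids)
    for chain in model.chains:
        if len(chain) <= peptide_max_len and chain.chain_id not in mapped:
            chain.entity_kind = EntityKind.PEPTIDE
        else:
            chain.entity_kind = EntityKind.PROTEIN
    for lig in model.ligands:
        if lig.comp_id in WATER_NAMES:
            lig.category = LigandCategory.WATER
        else:
            lig.category = ligand_dict.get(lig.comp_id, LigandCategory.OTHER)
        lig.display = "hidden" if lig.category in HIDDEN_CATEGORIES else "shown"
    return model
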