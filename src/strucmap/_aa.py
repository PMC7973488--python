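"""Amino-acid tables: naming, and the side-chain chemistry used for contact typing.

The donor/acceptor/charge/apolar assignments follow common structural-biology
practice for the 20 standard residues; they are data, not configuration —
geometric cutoffs live in :class:`strucmap.interactions.GeometryConfig`.
"""

from __future__ import annotations

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}

# Frequent nonstandard residues mapped to their parent standard residue.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "CME": "CYS",
    "MLY": "LYS",
    "HYP": "PRO",
    "PCA": "GLU",  # pyroglutamate
    "KCX": "LYS",
    "SEC": "CYS",  # selenocysteine (closest standard parent)
}

STANDARD_AA3 = frozenset(AA_3TO1)
POLYMER_AA3 = STANDARD_AA3 | frozenset(NONSTANDARD_PARENT)


def three_to_one(res_name: str) -> str:
    """One-letter code for a 3-letter residue name; unknown names give 'X'."""
    name = res_name.upper()
    if name in AA_3TO1:
        return AA_3TO1[name]
    if name in NONSTANDARD_PARENT:
        return AA_3TO1[NONSTANDARD_PARENT[name]]
    return "X"


def is_polymer_residue(res_name: str) -> bool:
    return res_name.upper() in POLYMER_AA3


def _parent(res_name: str) -> str:
    name = res_name.upper()
    return NONSTANDARD_PARENT.get(name, name)


# --- hydrogen bonding (heavy-atom proxy; no hydrogens required) -------------
# donor atom -> antecedent atom used for the antecedent-donor-acceptor angle.
# Backbone N (all residues except PRO) donates; antecedent CA.
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "TRP": {"NE1": "CD1"},
    "CYS": {"SG": "CB"},
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

BACKBONE_DONOR = "N"          # except PRO
BACKBONE_DONOR_ANTECEDENT = "CA"
BACKBONE_ACCEPTORS = ("O", "OXT")


def donor_atoms(res_name: str, *, is_proline_ok: bool = True) -> dict[str, str]:
    """Map of donor heavy atom -> antecedent atom for a residue type."""
    parent = _parent(res_name)
    out: dict[str, str] = {}
    if parent != "PRO":
        out[BACKBONE_DONOR] = BACKBONE_DONOR_ANTECEDENT
    out.update(SIDECHAIN_DONORS.get(parent, {}))
    return out


def acceptor_atoms(res_name: str) -> tuple[str, ...]:
    parent = _parent(res_name)
    return BACKBONE_ACCEPTORS + SIDECHAIN_ACCEPTORS.get(parent, ())


# --- formal charges ---------------------------------------------------------
# His is treated as potentially cationic (both ring nitrogens); protonation is
# not inferred.  N-/C-terminal charges are handled by the caller, which knows
# chain topology.
CATIONIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

ANIONIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# phosphate oxygens (phospho-residues and nucleotide-like ligands)
PHOSPHATE_O_NAMES = frozenset(
    {"O1P", "O2P", "O3P", "OP1", "OP2", "OP3", "O1G", "O2G", "O3G",
     "O1B", "O2B", "O3B", "O1A", "O2A", "O3A"}
)


def cationic_atoms(res_name: str) -> tuple[str, ...]:
    return CATIONIC_ATOMS.get(_parent(res_name), ())


def anionic_atoms(res_name: str) -> tuple[str, ...]:
    return ANIONIC_ATOMS.get(_parent(res_name), ())


# --- hydrophobic (apolar) carbons ------------------------------------------
# Side-chain carbons not bonded to O/N/S polar context; ligand carbons are all
# treated as apolar (documented simplification).
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "CE", "SD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}


def apolar_atoms(res_name: str) -> tuple[str, ...]:
    return APOLAR_CARBONS.get(_parent(res_name), ())


# --- aromatic rings ---------------------------------------------------------
# ring label -> ordered atom names; all listed atoms must be present for the
# ring centroid/plane to be computed.
AROMATIC_RINGS: dict[str, dict[str, tuple[str, ...]]] = {
    "PHE": {"ring6": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TYR": {"ring6": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "HIS": {"ring5": ("CG", "ND1", "CD2", "CE1", "NE2")},
    "TRP": {
        "ring5": ("CG", "CD1", "NE1", "CE2", "CD2"),
        "ring6": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    },
}


def aromatic_rings(res_name: str) -> dict[str, tuple[str, ...]]:
    return AROMATIC_RINGS.get(_parent(res_name), {})
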