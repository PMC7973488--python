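"""Protein-level variant parsing and structure-presence mapping.

The grammar follows HGVS-protein short forms (an optional ``p.`` prefix is
accepted and stripped; three-letter residue codes are normalized to
one-letter): missense ``V600E``, nonsense ``R130*``, deletion
``E746_A750del``, insertion ``D770_N771insNPG``, duplication
``A767_V769dup``, frameshift ``N1068fs``.  Effect annotations (activating /
inactivating / neutral / free text) are curated externally and passed
through verbatim; this module computes only position logic: which variant
positions are resolved in a given renumbered chain (shown with a white
background on the website) and which are absent (shaded).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._aa import AA_1TO3, AA_3TO1
from .reference_map import RenumberedChain

VARIANT_TYPES = ("missense", "nonsense", "deletion", "insertion",
                 "duplication", "frameshift")


class VariantSyntaxError(ValueError):
    def __init__(self, raw: str, message: str):
        super().__init__(f"cannot parse variant {raw!r}: {message}")
        self.raw = raw


@dataclass
class VariantRecord:
    raw: str
    type: str
    positions: tuple[int, int]  # inclusive reference interval
    ref_aa: str = ""
    alt_aa: str = ""
    effect: str = "unknown"
    source: str = ""
    detail: str = ""
    ptm: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.positions
        if lo < 1 or hi < lo:
            raise VariantSyntaxError(self.raw, f"bad position interval {self.positions}")
        if self.type == "missense" and (lo != hi or self.ref_aa == self.alt_aa):
            raise VariantSyntaxError(self.raw, "missense needs one position and ref != alt")
        if self.type == "nonsense" and self.alt_aa != "*":
            raise VariantSyntaxError(self.raw, "nonsense alt must be a stop")

    def position_list(self) -> list[int]:
        """Reference positions this variant touches on a structure.

        Frameshift and nonsense variants map to their start position only —
        the downstream truncation is annotation, not geometry.  Insertions
        touch their two flanking positions.
        """
        lo, hi = self.positions
        if self.type in ("nonsense", "frameshift"):
            return [lo]
        if self.type == "insertion":
            return [lo, hi]
        return list(range(lo, hi + 1))

    def canonical(self) -> str:
        """Canonical one-letter short form; re-parses to an equal record."""
        lo, hi = self.positions
        if self.type == "missense":
            return f"{self.ref_aa}{lo}{self.alt_aa}"
        if self.type == "nonsense":
            return f"{self.ref_aa}{lo}*"
        if self.type == "frameshift":
            return f"{self.ref_aa}{lo}fs"
        span = f"{self.ref_aa[0]}{lo}" if lo == hi else f"{self.ref_aa[0]}{lo}_{self.ref_aa[1]}{hi}"
        if self.type == "deletion":
            return f"{span}del"
        if self.type == "duplication":
            return f"{span}dup"
        if self.type == "insertion":
            return f"{self.ref_aa[0]}{lo}_{self.ref_aa[1]}{hi}ins{self.alt_aa}"
        raise AssertionError(self.type)


_AA3_GROUP = "|".join(AA_3TO1)
_AA = rf"(?:[A-Z]|(?:{_AA3_GROUP.title()})|(?:{_AA3_GROUP}))"

_RE_MISSENSE = re.compile(rf"^({_AA})(\d+)({_AA})$")
_RE_NONSENSE = re.compile(rf"^({_AA})(\d+)(?:\*|Ter|X)$")
_RE_RANGE_OP = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?(del|dup)$")
_RE_INSERT = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)ins((?:{_AA})+)$")
_RE_FRAMESHIFT = re.compile(rf"^({_AA})(\d+)fs(?:\*?\d+|Ter\d*)?$")


def _one(aa_token: str, raw: str) -> str:
    """Normalize a 1- or 3-letter residue token to one-letter."""
    if len(aa_token) == 1:
        if aa_token not in AA_1TO3:
            raise VariantSyntaxError(raw, f"unknown residue letter {aa_token!r}")
        return aa_token
    code = aa_token.upper()
    if code not in AA_3TO1:
        raise VariantSyntaxError(raw, f"unknown residue code {aa_token!r}")
    return AA_3TO1[code]


def _split_aa_run(run: str, raw: str) -> str:
    """Inserted-sequence token: all-1-letter or all-3-letter run."""
    if re.fullmatch(r"[A-Z]+", run) and all(c in AA_1TO3 for c in run):
        return run
    out = []
    if len(run) % 3 == 0:
        for i in range(0, len(run), 3):
            out.append(_one(run[i:i + 3], raw))
        return "".join(out)
    raise VariantSyntaxError(raw, f"bad inserted sequence {run!r}")


def parse_variant(raw: str) -> VariantRecord:
    """Parse one protein variant string into a typed record.

    Raises :class:`VariantSyntaxError` for unparseable strings (the message
    carries the offending token) and for zero/invalid positions.
    """
    if not raw or not raw.strip():
        raise VariantSyntaxError(raw, "empty string")
    s = raw.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    s = s.replace("(", "").replace(")", "")

    m = _RE_NONSENSE.match(s)
    if m:
        return VariantRecord(raw, "nonsense", (int(m.group(2)),) * 2,
                             ref_aa=_one(m.group(1), raw), alt_aa="*")
    m = _RE_FRAMESHIFT.match(s)
    if m:
        return VariantRecord(raw, "frameshift", (int(m.group(2)),) * 2,
                             ref_aa=_one(m.group(1), raw))
    m = _RE_INSERT.match(s)
    if m:
        lo, hi = int(m.group(2)), int(m.group(4))
        if hi != lo + 1:
            raise VariantSyntaxError(raw, f"insertion flanks must be adjacent ({lo}_{hi})")
        return VariantRecord(raw, "insertion", (lo, hi),
                             ref_aa=_one(m.group(1), raw) + _one(m.group(3), raw),
                             alt_aa=_split_aa_run(m.group(5), raw))
    m = _RE_RANGE_OP.match(s)
    if m:
        lo = int(m.group(2))
        hi = int(m.group(4)) if m.group(4) else lo
        first = _one(m.group(1), raw)
        last = _one(m.group(3), raw) if m.group(3) else first
        vtype = "deletion" if m.group(5) == "del" else "duplication"
        return VariantRecord(raw, vtype, (lo, hi), ref_aa=first + last)
    m = _RE_MISSENSE.match(s)
    if m:
        return VariantRecord(raw, "missense", (int(m.group(2)),) * 2,
                             ref_aa=_one(m.group(1), raw), alt_aa=_one(m.group(3), raw))
    raise VariantSyntaxError(raw, f"no variant grammar matches {s!r}")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

@dataclass
class RejectedRow:
    row: int
    raw: str
    reason: str


MANDATORY_COLUMNS = ("raw", "effect", "source")


def read_variant_table(path) -> tuple[list[VariantRecord], list[RejectedRow]]:
    """Read a variant table (TSV with columns raw/effect/source[/detail/ptm],
    or a JSON list of objects with the same keys).

    Every row either parses into a record or lands in the rejects list with
    a reason; PTM rows (e.g. phosphosites) are flagged, not interpreted.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
        df = pd.DataFrame(rows)
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            return [], []
    if df.empty and not df.columns.size:
        return [], []
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"variant table {path} lacks mandatory columns: {missing_cols}")
    records: list[VariantRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        raw = str(row["raw"]).strip()
        ptm = str(row.get("ptm", "")).strip().lower() in ("1", "true", "yes")
        try:
            rec = parse_variant(raw)
        except VariantSyntaxError as exc:
            rejects.append(RejectedRow(int(i), raw, str(exc)))
            continue
        rec.effect = str(row.get("effect", "")) or "unknown"
        rec.source = str(row.get("source", ""))
        rec.detail = str(row.get("detail", ""))
        rec.ptm = ptm
        records.append(rec)
    return records, rejects


def variants_by_position(records: list[VariantRecord]) -> dict[int, list[VariantRecord]]:
    out: dict[int, list[VariantRecord]] = {}
    for rec in records:
        for p in rec.position_list():
            out.setdefault(p, []).append(rec)
    return out


# ---------------------------------------------------------------------------
# structure presence
# ---------------------------------------------------------------------------

@dataclass
class VariantPresence:
    variant: VariantRecord
    status: str  # full | partial | absent
    present_positions: list[int] = field(default_factory=list)
    absent_positions: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def map_variant_presence(
    v: VariantRecord,
    rc: RenumberedChain,
    reference_sequence: Optional[str] = None,
) -> VariantPresence:
    """Check which of a variant's positions are resolved in a renumbered
    chain (full / partial / absent).

    For missense variants, a mismatch between the variant's stated reference
    residue and the actual reference sequence at that position is reported
    as a warning, never an error.
    """
    resolved = rc.resolved_positions()
    pos = v.position_list()
    present = sorted(p for p in pos if p in resolved)
    absent = sorted(p for p in pos if p not in resolved)
    status = "full" if not absent else ("absent" if not present else "partial")
    warnings: list[str] = []
    if v.type == "missense" and reference_sequence is not None:
        p = v.positions[0]
        if 1 <= p <= len(reference_sequence) and reference_sequence[p - 1] != v.ref_aa:
            warnings.append(
                f"reference-mismatch: variant states {v.ref_aa}{p} but reference "
                f"has {reference_sequence[p - 1]} at {p}"
            )
    return VariantPresence(v, status, present, absent, warnings)


def presence_table(presences: list[VariantPresence]) -> pd.DataFrame:
    rows = []
    for p in presences:
        rows.append({
            "variant": p.variant.canonical(),
            "type": p.variant.type,
            "effect": p.variant.effect,
            "ptm": p.variant.ptm,
            "status": p.status,
            "present_positions": ",".join(map(str, p.present_positions)),
            "absent_positions": ",".join(map(str, p.absent_positions)),
            "warnings": ";".join(p.warnings),
        })
    cols = ["variant", "type", "effect", "ptm", "status",
            "present_positions", "absent_positions", "warnings"]
    return pd.DataFrame(rows, columns=cols)
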