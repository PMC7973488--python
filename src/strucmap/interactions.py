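"""Residue micro-environment analysis: neighbours and typed contacts.

Given a query residue (or ligand) in a structure, find every residue or
ligand with heavy atoms nearby — optionally across chains, for bound
partners — and type the molecular interactions between them: hydrogen
bonds, ionic interactions (salt bridges), cation–π, π-stacking, and
hydrophobic contacts.

Hydrogens are not required: hydrogen bonds are detected on heavy-atom
donor/acceptor distance with the antecedent–donor–acceptor angle as a
directionality proxy.  His rings are treated as both aromatic and
potentially cationic; protonation is never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from . import _aa
from .io_structures import LigandEntry, Residue, ResidueKey, StructureModel

Entity = Union[Residue, LigandEntry]

CONTACT_KINDS = ("hbond", "ionic", "cation_pi", "pi_stack", "hydrophobic")


class LookupError_(KeyError):
    """Query residue/ligand key not present in the structure."""


@dataclass
class GeometryConfig:
    """Geometric cutoffs for neighbour search and contact typing (Å, degrees).

    Defaults follow common structural-biology practice; the underlying
    interaction types come from the display conventions of interactive
    structure viewers, which publish no cutoffs, so every value here is
    configurable and version-pinned with the package.
    """

    neighbor_radius: float = 5.0
    hbond_max: float = 3.5
    hbond_min_angle: float = 90.0
    ionic_max: float = 4.0
    hydrophobic_max: float = 4.5
    pi_centroid_max: float = 5.5
    pi_parallel_max_tilt: float = 30.0
    cation_pi_max: float = 6.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    def max_cutoff(self) -> float:
        return max(self.hbond_max, self.ionic_max, self.hydrophobic_max,
                   self.pi_centroid_max, self.cation_pi_max)


@dataclass
class InteractionContact:
    kind: str
    partner_a: tuple[ResidueKey, str]  # (entity key, atom or group label)
    partner_b: tuple[ResidueKey, str]
    distance: float
    angle: Optional[float] = None
    inter_chain: bool = False
    note: str = ""

    def to_row(self) -> dict:
        (ka, la), (kb, lb) = self.partner_a, self.partner_b
        return {
            "kind": self.kind,
            "chainA": ka[0], "resA": f"{ka[1]}{ka[2]}", "atomA": la,
            "chainB": kb[0], "resB": f"{kb[1]}{kb[2]}", "atomB": lb,
            "distance": round(self.distance, 3),
            "angle": (round(self.angle, 1) if self.angle is not None else ""),
            "inter_chain": self.inter_chain,
        }


# ---------------------------------------------------------------------------
# entity helpers
# ---------------------------------------------------------------------------

def _entities(model: StructureModel) -> list[Entity]:
    out: list[Entity] = []
    for chain in model.chains:
        out.extend(chain.residues)
    out.extend(model.ligands)
    return out


def _entity_key(e: Entity) -> ResidueKey:
    return e.key


def _entity_chain(e: Entity) -> str:
    return e.chain_id


def _res_name(e: Entity) -> str:
    return e.res_name if isinstance(e, Residue) else e.comp_id


def _is_terminal(chain_residues: list[Residue], res: Residue) -> tuple[bool, bool]:
    if not chain_residues:
        return False, False
    return chain_residues[0] is res, chain_residues[-1] is res


def get_entity(model: StructureModel, key: ResidueKey) -> Entity:
    ent = model.find_entity(tuple(key))
    if ent is None:
        raise LookupError_(f"no residue or ligand with key {key}")
    return ent


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def neighbors_within(
    model: StructureModel,
    query: ResidueKey,
    cfg: GeometryConfig = GeometryConfig(),
    include_other_chains: bool = False,
) -> list[ResidueKey]:
    """Keys of residues/ligands with a heavy atom within ``neighbor_radius``
    of any query heavy atom.

    Other chains are included only when ``include_other_chains`` is set (the
    multi-chain display behaviour); the query itself is never a neighbour.
    """
    q = get_entity(model, query)
    q_coords = np.array([a.coords for a in q.heavy_atoms()])
    if q_coords.size == 0:
        return []
    tree = cKDTree(q_coords)
    out: list[ResidueKey] = []
    for ent in _entities(model):
        if ent is q:
            continue
        if not include_other_chains and _entity_chain(ent) != _entity_chain(q):
            continue
        coords = [a.coords for a in ent.heavy_atoms()]
        if not coords:
            continue
        d, _ = tree.query(np.array(coords), k=1)
        if np.min(d) <= cfg.neighbor_radius:
            out.append(_entity_key(ent))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# contact predicates
# ---------------------------------------------------------------------------

def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _donors(ent: Entity, model: StructureModel) -> list[tuple[np.ndarray, Optional[np.ndarray], str]]:
    """(donor coords, antecedent coords or None, atom name)."""
    out = []
    if isinstance(ent, Residue):
        table = _aa.donor_atoms(ent.res_name)
        for dname, aname in table.items():
            d = ent.atom(dname)
            if d is None:
                continue
            ante = ent.atom(aname)
            out.append((d.coords, ante.coords if ante else None, dname))
    return out


def _acceptors(ent: Entity) -> list[tuple[np.ndarray, str]]:
    out = []
    if isinstance(ent, Residue):
        for name in _aa.acceptor_atoms(ent.res_name):
            a = ent.atom(name)
            if a is not None:
                out.append((a.coords, name))
    else:
        # ligand oxygens/nitrogens accept (simplified typing)
        for a in ent.heavy_atoms():
            if a.element.upper() in ("O", "N"):
                out.append((a.coords, a.name))
    return out


def _cationic(ent: Entity, model: StructureModel) -> list[tuple[np.ndarray, str]]:
    out = []
    if isinstance(ent, Residue):
        for name in _aa.cationic_atoms(ent.res_name):
            a = ent.atom(name)
            if a is not None:
                out.append((a.coords, name))
        chain = model.chain(ent.chain_id)
        if chain is not None and chain.residues and chain.residues[0] is ent:
            n = ent.atom("N")  # free N-terminus
            if n is not None:
                out.append((n.coords, "N"))
    return out


def _anionic(ent: Entity, model: StructureModel) -> list[tuple[np.ndarray, str]]:
    out = []
    if isinstance(ent, Residue):
        for name in _aa.anionic_atoms(ent.res_name):
            a = ent.atom(name)
            if a is not None:
                out.append((a.coords, name))
        chain = model.chain(ent.chain_id)
        if chain is not None and chain.residues and chain.residues[-1] is ent:
            oxt = ent.atom("OXT")  # free C-terminus
            if oxt is not None:
                out.append((oxt.coords, "OXT"))
        for a in ent.atoms:
            if a.name in _aa.PHOSPHATE_O_NAMES:
                out.append((a.coords, a.name))
    else:
        for a in ent.heavy_atoms():
            if a.name in _aa.PHOSPHATE_O_NAMES:
                out.append((a.coords, a.name))
    return out


def _apolar(ent: Entity) -> list[tuple[np.ndarray, str]]:
    out = []
    if isinstance(ent, Residue):
        for name in _aa.apolar_atoms(ent.res_name):
            a = ent.atom(name)
            if a is not None:
                out.append((a.coords, name))
    else:
        if _res_name(ent).upper() in ("HOH", "DOD", "WAT"):
            return []
        for a in ent.heavy_atoms():
            if a.element.upper() == "C":
                out.append((a.coords, a.name))
    return out


def _rings(ent: Entity) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """(centroid, unit normal, ring label) for each complete aromatic ring."""
    out = []
    if not isinstance(ent, Residue):
        return out
    for label, names in _aa.aromatic_rings(ent.res_name).items():
        coords = []
        for n in names:
            a = ent.atom(n)
            if a is None:
                break
            coords.append(a.coords)
        else:
            arr = np.array(coords)
            centroid = arr.mean(axis=0)
            centered = arr - centroid
            # ring plane normal = smallest singular vector
            _, _, vt = np.linalg.svd(centered)
            normal = vt[-1]
            out.append((centroid, normal / np.linalg.norm(normal), label))
    return out


def _tilt(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes, folded to [0, 90] degrees."""
    cosang = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, cosang)))


def _pair_contacts(
    a: Entity, b: Entity, model: StructureModel, kinds: Iterable[str],
    cfg: GeometryConfig,
) -> list[InteractionContact]:
    """All typed contacts between two distinct entities (directionless)."""
    inter = _entity_chain(a) != _entity_chain(b)
    ka, kb = _entity_key(a), _entity_key(b)
    found: list[InteractionContact] = []
    kinds = set(kinds)

    if "hbond" in kinds:
        seen: set[tuple[str, str]] = set()
        for don, acc in ((a, b), (b, a)):
            for dxyz, antexyz, dname in _donors(don, model):
                for axyz, aname in _acceptors(acc):
                    d = _dist(dxyz, axyz)
                    if d <= 0 or d > cfg.hbond_max:
                        continue
                    ang = None
                    if antexyz is not None:
                        ang = _angle(antexyz, dxyz, axyz)
                        if ang < cfg.hbond_min_angle:
                            continue
                    pair = (dname, aname) if don is a else (aname, dname)
                    if pair in seen:
                        continue
                    seen.add(pair)
                    found.append(InteractionContact(
                        "hbond",
                        (ka, pair[0]), (kb, pair[1]),
                        d, ang, inter))

    if "ionic" in kinds:
        for cat_e, an_e in ((a, b), (b, a)):
            for cxyz, cname in _cationic(cat_e, model):
                for axyz, aname in _anionic(an_e, model):
                    d = _dist(cxyz, axyz)
                    if 0 < d <= cfg.ionic_max:
                        pair = (cname, aname) if cat_e is a else (aname, cname)
                        found.append(InteractionContact(
                            "ionic", (ka, pair[0]), (kb, pair[1]), d, None, inter))

    if "hydrophobic" in kinds:
        for cxyz, cname in _apolar(a):
            for dxyz, dname in _apolar(b):
                d = _dist(cxyz, dxyz)
                if 0 < d <= cfg.hydrophobic_max:
                    found.append(InteractionContact(
                        "hydrophobic", (ka, cname), (kb, dname), d, None, inter))

    if "pi_stack" in kinds:
        for c1, n1, l1 in _rings(a):
            for c2, n2, l2 in _rings(b):
                d = _dist(c1, c2)
                if 0 < d <= cfg.pi_centroid_max:
                    tilt = _tilt(n1, n2)
                    note = ("parallel" if tilt <= cfg.pi_parallel_max_tilt
                            else "tilted")
                    found.append(InteractionContact(
                        "pi_stack", (ka, l1), (kb, l2), d, tilt, inter, note))

    if "cation_pi" in kinds:
        for cat_e, ring_e in ((a, b), (b, a)):
            for cxyz, cname in _cationic(cat_e, model):
                for ctr, nrm, label in _rings(ring_e):
                    d = _dist(cxyz, ctr)
                    if 0 < d <= cfg.cation_pi_max:
                        pair = (cname, label) if cat_e is a else (label, cname)
                        found.append(InteractionContact(
                            "cation_pi", (ka, pair[0]), (kb, pair[1]), d, None, inter))

    return found


def find_contacts(
    model: StructureModel,
    query: ResidueKey,
    kinds: Iterable[str] = CONTACT_KINDS,
    cfg: GeometryConfig = GeometryConfig(),
    include_other_chains: bool = True,
) -> list[InteractionContact]:
    """Typed contacts between the query residue/ligand and its environment.

    Results are sorted by (kind, distance, partner key); a query lacking the
    chemistry for a requested kind (e.g. π-stacking on glycine) simply
    contributes no contacts of that kind.
    """
    kinds = list(kinds)
    if not kinds:
        raise ValueError("kinds must be non-empty")
    unknown = set(kinds) - set(CONTACT_KINDS)
    if unknown:
        raise ValueError(f"unknown contact kinds: {sorted(unknown)}")
    q = get_entity(model, query)
    q_coords = np.array([a.coords for a in q.heavy_atoms()])
    if q_coords.size == 0:
        return []
    tree = cKDTree(q_coords)
    reach = cfg.max_cutoff() + 8.0  # margin covers ring-centroid geometry
    out: list[InteractionContact] = []
    for ent in _entities(model):
        if ent is q:
            continue
        if not include_other_chains and _entity_chain(ent) != _entity_chain(q):
            continue
        coords = [a.coords for a in ent.heavy_atoms()]
        if not coords:
            continue
        d, _ = tree.query(np.array(coords), k=1)
        if np.min(d) > reach:
            continue
        out.extend(_pair_contacts(q, ent, model, kinds, cfg))
    out.sort(key=lambda c: (c.kind, round(c.distance, 6), c.partner_b, c.partner_a))
    return out


# ---------------------------------------------------------------------------
# environment report
# ---------------------------------------------------------------------------

def residue_environment_report(
    model: StructureModel,
    query: ResidueKey,
    cfg: GeometryConfig = GeometryConfig(),
    variants_by_position: Optional[dict[int, list]] = None,
    renumbered=None,
    include_other_chains: bool = True,
) -> dict:
    """Combined report: neighbours, typed contacts, and annotated variants
    on the query and its neighbour residues.

    ``variants_by_position`` maps reference positions to variant records
    (each with ``raw`` and ``effect`` attributes); ``renumbered`` (a
    RenumberedChain per mapped chain id) translates author keys to
    reference positions for the join.  Effect annotations are passed
    through verbatim.
    """
    q = get_entity(model, query)
    neigh = neighbors_within(model, query, cfg, include_other_chains)
    contacts = find_contacts(model, query, CONTACT_KINDS, cfg, include_other_chains)
    report = {
        "query": {"key": list(query), "name": _res_name(q)},
        "neighbors": [list(k) for k in neigh],
        "contacts": [c.to_row() for c in contacts],
    }
    if variants_by_position is not None:
        rc_by_chain = {}
        if renumbered is not None:
            rc_by_chain = {rc.chain_id: rc for rc in (
                renumbered if isinstance(renumbered, (list, tuple)) else [renumbered])}

        def ref_pos_of(key: ResidueKey) -> Optional[int]:
            rc = rc_by_chain.get(key[0])
            return rc.position_of(tuple(key)) if rc is not None else None

        def annotate(keys) -> list[dict]:
            rows = []
            for k in keys:
                p = ref_pos_of(k)
                if p is None:
                    continue
                for v in variants_by_position.get(p, []):
                    rows.append({
                        "residue": list(k), "ref_pos": p,
                        "variant": getattr(v, "raw", str(v)),
                        "effect": getattr(v, "effect", ""),
                    })
            return rows

        report["query_variants"] = annotate([tuple(query)])
        report["neighbor_variants"] = annotate([tuple(k) for k in neigh])
    return report


def contacts_table(contacts: list[InteractionContact]):
    import pandas as pd

    cols = ["kind", "chainA", "resA", "atomA", "chainB", "resB", "atomB",
            "distance", "angle", "inter_chain"]
    return pd.DataFrame([c.to_row() for c in contacts], columns=cols)
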