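"""Contact typing against an independent brute-force geometric oracle.

The oracle re-implements every geometric predicate with plain Python
``math`` over an exhaustive all-pairs scan (no spatial index, no shared
geometry code), deriving ring planes from cross products instead of SVD.
Chemistry assignments (which atoms donate, accept, carry charge, etc.) are
shared data tables; the geometry and search logic are independent.
"""

import math

import numpy as np
import pytest

from strucmap import _aa
from strucmap.fixtures import make_contact_scene
from strucmap.interactions import (
    CONTACT_KINDS,
    GeometryConfig,
    find_contacts,
    neighbors_within,
)
from strucmap.io_structures import (
    Atom,
    ChainModel,
    Residue,
    StructureHeader,
    StructureModel,
)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _d(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _ang(a, b, c):
    v1 = [a[i] - b[i] for i in range(3)]
    v2 = [c[i] - b[i] for i in range(3)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    cos = sum(x * y for x, y in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def _coords(res, name):
    a = res.atom(name)
    return None if a is None else tuple(a.coords)


def _ring_data(res):
    rings = []
    for label, names in _aa.aromatic_rings(res.res_name).items():
        pts = [_coords(res, n) for n in names]
        if any(p is None for p in pts):
            continue
        ctr = tuple(sum(p[i] for p in pts) / len(pts) for i in range(3))
        v1 = [pts[1][i] - pts[0][i] for i in range(3)]
        v2 = [pts[2][i] - pts[0][i] for i in range(3)]
        nrm = (v1[1] * v2[2] - v1[2] * v2[1],
               v1[2] * v2[0] - v1[0] * v2[2],
               v1[0] * v2[1] - v1[1] * v2[0])
        mag = math.sqrt(sum(x * x for x in nrm))
        rings.append((ctr, tuple(x / mag for x in nrm), label))
    return rings


def _cationic_oracle(res, model):
    out = [(_coords(res, n), n) for n in _aa.cationic_atoms(res.res_name)
           if _coords(res, n)]
    chain = model.chain(res.chain_id)
    if chain is not None and chain.residues and chain.residues[0] is res:
        p = _coords(res, "N")
        if p:
            out.append((p, "N"))
    return out


def _anionic_oracle(res, model):
    out = [(_coords(res, n), n) for n in _aa.anionic_atoms(res.res_name)
           if _coords(res, n)]
    chain = model.chain(res.chain_id)
    if chain is not None and chain.residues and chain.residues[-1] is res:
        p = _coords(res, "OXT")
        if p:
            out.append((p, "OXT"))
    for a in res.atoms:
        if a.name in _aa.PHOSPHATE_O_NAMES:
            out.append((tuple(a.coords), a.name))
    return out


def brute_force_contacts(model, query_key, cfg):
    """Signature set {(kind, atomA, keyB, atomB, round(dist, 5))} from an
    exhaustive scan."""
    residues = [r for c in model.chains for r in c.residues]
    q = next(r for r in residues if r.key == query_key)
    sigs = set()
    for other in residues:
        if other is q:
            continue
        # hydrogen bonds (both directions, deduplicated on atom pair)
        seen = set()
        for don, acc in ((q, other), (other, q)):
            donors = _aa.donor_atoms(don.res_name)
            for dname, antename in donors.items():
                dxyz = _coords(don, dname)
                if dxyz is None:
                    continue
                for aname in _aa.acceptor_atoms(acc.res_name):
                    axyz = _coords(acc, aname)
                    if axyz is None:
                        continue
                    dist = _d(dxyz, axyz)
                    if dist <= 0 or dist > cfg.hbond_max:
                        continue
                    antexyz = _coords(don, antename)
                    if antexyz is not None and _ang(antexyz, dxyz, axyz) < cfg.hbond_min_angle:
                        continue
                    pair = (dname, aname) if don is q else (aname, dname)
                    if pair in seen:
                        continue
                    seen.add(pair)
                    sigs.add(("hbond", pair[0], other.key, pair[1], round(dist, 5)))
        # ionic
        for cat_r, an_r in ((q, other), (other, q)):
            for cxyz, cname in _cationic_oracle(cat_r, model):
                for axyz, aname in _anionic_oracle(an_r, model):
                    dist = _d(cxyz, axyz)
                    if 0 < dist <= cfg.ionic_max:
                        pair = (cname, aname) if cat_r is q else (aname, cname)
                        sigs.add(("ionic", pair[0], other.key, pair[1], round(dist, 5)))
        # hydrophobic
        for n1 in _aa.apolar_atoms(q.res_name):
            p1 = _coords(q, n1)
            if p1 is None:
                continue
            for n2 in _aa.apolar_atoms(other.res_name):
                p2 = _coords(other, n2)
                if p2 is None:
                    continue
                dist = _d(p1, p2)
                if 0 < dist <= cfg.hydrophobic_max:
                    sigs.add(("hydrophobic", n1, other.key, n2, round(dist, 5)))
        # pi stacking
        for c1, _n1, l1 in _ring_data(q):
            for c2, _n2, l2 in _ring_data(other):
                dist = _d(c1, c2)
                if 0 < dist <= cfg.pi_centroid_max:
                    sigs.add(("pi_stack", l1, other.key, l2, round(dist, 5)))
        # cation-pi
        for cat_r, ring_r in ((q, other), (other, q)):
            for cxyz, cname in _cationic_oracle(cat_r, model):
                for ctr, _nrm, label in _ring_data(ring_r):
                    dist = _d(cxyz, ctr)
                    if 0 < dist <= cfg.cation_pi_max:
                        pair = (cname, label) if cat_r is q else (label, cname)
                        sigs.add(("cation_pi", pair[0], other.key, pair[1],
                                  round(dist, 5)))
    return sigs


def _signatures(contacts):
    return {(c.kind, c.partner_a[1], c.partner_b[0], c.partner_b[1],
             round(c.distance, 5)) for c in contacts}


def brute_force_neighbors(model, query_key, radius, include_other_chains):
    entities = [r for c in model.chains for r in c.residues] + list(model.ligands)
    q = next(e for e in entities if e.key == query_key)
    out = []
    for e in entities:
        if e is q:
            continue
        if not include_other_chains and e.chain_id != q.chain_id:
            continue
        dmin = min((_d(tuple(a.coords), tuple(b.coords))
                    for a in q.heavy_atoms() for b in e.heavy_atoms()),
                   default=math.inf)
        if dmin <= radius:
            out.append(e.key)
    return sorted(out)


# ---------------------------------------------------------------------------
# oracle equivalence on random scenes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_contacts_match_brute_force(seed):
    model = make_contact_scene(seed)
    cfg = GeometryConfig()
    for chain in model.chains:
        for res in chain.residues:
            got = _signatures(find_contacts(model, res.key, CONTACT_KINDS, cfg))
            exp = brute_force_contacts(model, res.key, cfg)
            assert got == exp, f"seed {seed} query {res.key}"


@pytest.mark.parametrize("seed", [0, 3, 6])
def test_neighbors_match_brute_force(seed):
    model = make_contact_scene(seed)
    cfg = GeometryConfig()
    for chain in model.chains:
        for res in chain.residues:
            for other in (False, True):
                got = neighbors_within(model, res.key, cfg, include_other_chains=other)
                assert got == brute_force_neighbors(model, res.key,
                                                    cfg.neighbor_radius, other)


def test_contact_symmetry():
    model = make_contact_scene(4)
    residues = [r for c in model.chains for r in c.residues]
    cfg = GeometryConfig()
    by_query = {r.key: find_contacts(model, r.key, CONTACT_KINDS, cfg)
                for r in residues}
    for key, contacts in by_query.items():
        for c in contacts:
            partner = c.partner_b[0]
            mirrored = by_query[partner]
            assert any(m.partner_b[0] == key and m.kind == c.kind
                       and abs(m.distance - c.distance) < 1e-9
                       for m in mirrored), (key, c)


def test_radius_monotonicity():
    model = make_contact_scene(5)
    res = model.chains[0].residues[0]
    small = set(map(tuple, neighbors_within(
        model, res.key, GeometryConfig(neighbor_radius=4.0), True)))
    large = set(map(tuple, neighbors_within(
        model, res.key, GeometryConfig(neighbor_radius=7.0), True)))
    assert small <= large


def test_deterministic_ordering():
    model = make_contact_scene(6)
    res = model.chains[0].residues[1]
    c1 = find_contacts(model, res.key)
    c2 = find_contacts(model, res.key)
    assert [(c.kind, c.partner_b, c.distance) for c in c1] == \
           [(c.kind, c.partner_b, c.distance) for c in c2]
    kinds = [c.kind for c in c1]
    assert kinds == sorted(kinds)


# ---------------------------------------------------------------------------
# constructed-geometry cases
# ---------------------------------------------------------------------------

def _res(ch, num, name, atoms):
    return Residue(ch, num, "", name, _aa.three_to_one(name),
                   [Atom(n, e, np.array(x)) for n, e, x in atoms])


def _model(*chains):
    return StructureModel(StructureHeader(entry_id="GEO1"),
                          [ChainModel(cid, list(rs)) for cid, rs in chains], [])


def test_salt_bridge_at_cutoff():
    lys = _res("A", 1, "LYS", [("CA", "C", (0, 0, 0)), ("CE", "C", (1, 0, 0)),
                               ("NZ", "N", (2, 0, 0))])
    glu = _res("A", 3, "GLU", [("CA", "C", (8, 0, 0)), ("CD", "C", (6.5, 0, 0)),
                               ("OE1", "O", (5.5, 0, 0)),
                               ("OE2", "O", (6.5, 1.2, 0))])
    m = _model(("A", [lys, glu]))
    contacts = find_contacts(m, ("A", 1, ""), ["ionic"])
    assert len(contacts) == 1
    c = contacts[0]
    assert c.kind == "ionic" and c.distance == pytest.approx(3.5)
    assert c.partner_a[1] == "NZ" and c.partner_b[1] == "OE1"
    # just beyond the 4.0 A cutoff: nothing
    glu_far = _res("A", 3, "GLU", [("CA", "C", (9, 0, 0)), ("CD", "C", (7.5, 0, 0)),
                                   ("OE1", "O", (6.1, 0, 0)),
                                   ("OE2", "O", (7.5, 1.2, 0))])
    m2 = _model(("A", [lys, glu_far]))
    assert find_contacts(m2, ("A", 1, ""), ["ionic"]) == []


def test_backbone_hydrogen_bond_linear():
    donor = _res("A", 5, "GLY", [("N", "N", (4.9, -0.3, 0)), ("CA", "C", (6.3, -0.3, 0))])
    acceptor = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0)), ("C", "C", (1.2, 0.5, 0)),
                                    ("O", "O", (2.0, -0.3, 0))])
    m = _model(("A", [acceptor, donor]))
    contacts = find_contacts(m, ("A", 5, ""), ["hbond"])
    assert len(contacts) == 1
    c = contacts[0]
    assert c.distance == pytest.approx(2.9) and c.angle == pytest.approx(180.0)


def test_hbond_rejected_by_angle():
    # acceptor on the same side as the antecedent: angle < 90 degrees
    donor = _res("A", 5, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (2.0, 0, 0))])
    acceptor = _res("A", 1, "ALA", [("CA", "C", (4.5, 0.6, 0)), ("C", "C", (3.6, 0.8, 0)),
                                    ("O", "O", (2.6, 1.4, 0))])
    m = _model(("A", [acceptor, donor]))
    assert find_contacts(m, ("A", 5, ""), ["hbond"]) == []


def test_glycine_has_no_pi_stack():
    gly = _res("A", 1, "GLY", [("CA", "C", (0, 0, 0))])
    phe = _res("A", 3, "PHE", [("CG", "C", (3, 0, 0)), ("CD1", "C", (4.2, 0.7, 0)),
                               ("CE1", "C", (5.4, 0, 0)), ("CZ", "C", (5.4, -1.4, 0)),
                               ("CE2", "C", (4.2, -2.1, 0)), ("CD2", "C", (3, -1.4, 0))])
    m = _model(("A", [gly, phe]))
    assert find_contacts(m, ("A", 1, ""), ["pi_stack"]) == []


def test_parallel_pi_stack_geometry():
    def ring(ch, num, z):
        atoms = []
        for j, name in enumerate(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]):
            a = math.radians(60 * j)
            atoms.append((name, "C", (1.39 * math.cos(a), 1.39 * math.sin(a), z)))
        return _res(ch, num, "PHE", atoms)

    m = _model(("A", [ring("A", 1, 0.0), ring("A", 3, 3.8)]))
    contacts = find_contacts(m, ("A", 1, ""), ["pi_stack"])
    assert len(contacts) == 1
    c = contacts[0]
    assert c.distance == pytest.approx(3.8)
    assert c.angle == pytest.approx(0.0, abs=1e-6)
    assert c.note == "parallel"


def test_other_chain_inclusion_flag():
    a = _res("A", 1, "LEU", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.4, 0, 0)),
                             ("CG", "C", (2.6, 0.8, 0)), ("CD1", "C", (3.9, 0.2, 0)),
                             ("CD2", "C", (2.6, 2.2, 0))])
    b = _res("B", 1, "LEU", [("CA", "C", (7.5, 0, 0)), ("CB", "C", (6.2, 0.4, 0)),
                             ("CG", "C", (5.5, 0.8, 0)), ("CD1", "C", (4.4, 0.1, 0)),
                             ("CD2", "C", (5.5, 2.2, 0))])
    m = _model(("A", [a]), ("B", [b]))
    assert neighbors_within(m, ("A", 1, ""), include_other_chains=False) == []
    got = neighbors_within(m, ("A", 1, ""), include_other_chains=True)
    assert got == [("B", 1, "")]
    contacts = find_contacts(m, ("A", 1, ""), ["hydrophobic"],
                             include_other_chains=True)
    assert contacts and all(c.inter_chain for c in contacts)
    assert find_contacts(m, ("A", 1, ""), ["hydrophobic"],
                         include_other_chains=False) == []


def test_isolated_residue_has_no_neighbors():
    a = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
    b = _res("A", 9, "ALA", [("CA", "C", (30, 0, 0)), ("CB", "C", (31.5, 0, 0))])
    m = _model(("A", [a, b]))
    assert neighbors_within(m, ("A", 1, "")) == []


def test_empty_kinds_rejected():
    m = _model(("A", [_res("A", 1, "ALA", [("CA", "C", (0, 0, 0))])]))
    with pytest.raises(ValueError):
        find_contacts(m, ("A", 1, ""), [])


def test_unknown_query_rejected():
    m = _model(("A", [_res("A", 1, "ALA", [("CA", "C", (0, 0, 0))])]))
    with pytest.raises(KeyError):
        find_contacts(m, ("A", 99, ""))
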