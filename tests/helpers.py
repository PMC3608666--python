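"""Hand-built systems and independent brute-force oracles for the tests.

Everything here recomputes geometry with explicit Python loops and its own
vector math, so oracle results never share code paths with the package
implementation they check.
"""

import math

import numpy as np

from idpmech.contacts import (
    CHARGE_GROUP_ATOMS,
    CONTACT_CUTOFF,
    ELECTROSTATIC_CUTOFF,
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
    MIN_SEQUENCE_SEPARATION,
    _SIDECHAIN_ACCEPTORS,
    _SIDECHAIN_DONORS,
)
from idpmech.system_model import SystemModel, classify_residue


def make_system(residues):
    """Build a SystemModel from a nested description.

    ``residues`` is a list of ``(chain, resid, resname, atoms)`` where
    ``atoms`` is a list of ``(atom_name, element, mass, (x, y, z))``.
    """
    res_chain, res_index, res_name = [], [], []
    atom_res, atom_name, element, masses, backbone, coords = [], [], [], [], [], []
    chains = []
    for chain, resid, resname, atoms in residues:
        if chain not in chains:
            chains.append(chain)
        rid = len(res_name)
        res_chain.append(chain)
        res_index.append(resid)
        res_name.append(resname)
        for name, elem, mass, xyz in atoms:
            atom_res.append(rid)
            atom_name.append(name)
            element.append(elem)
            masses.append(mass)
            backbone.append(name in ("N", "CA", "C", "O", "OXT"))
            coords.append(xyz)
    return SystemModel(
        chains=chains,
        res_chain=np.array(res_chain, dtype=object),
        res_index=np.array(res_index, dtype=int),
        res_name=np.array(res_name, dtype=object),
        res_class=np.array([classify_residue(n) for n in res_name], dtype=object),
        atom_res=np.array(atom_res, dtype=int),
        atom_name=np.array(atom_name, dtype=object),
        element=np.array(element, dtype=object),
        masses=np.array(masses, dtype=float),
        is_backbone=np.array(backbone, dtype=bool),
        reference_coords=np.array(coords, dtype=float),
    )


def two_cb_residues(d, resnames=("LEU", "LEU"), chain_pair=("A", "A"), resids=(1, 3)):
    """Two single-pseudo-side-chain residues with CB atoms ``d`` Å apart."""
    return make_system(
        [
            (
                chain_pair[0], resids[0], resnames[0],
                [("CA", "C", 13.0, (0.0, 0.0, 0.0)), ("CB", "C", 57.0, (1.5, 0.0, 0.0))],
            ),
            (
                chain_pair[1], resids[1], resnames[1],
                [("CA", "C", 13.0, (1.5 + d + 1.5, 0.0, 0.0)),
                 ("CB", "C", 57.0, (1.5 + d, 0.0, 0.0))],
            ),
        ]
    )


# ----------------------------------------------------------------------
# independent geometric oracles
# ----------------------------------------------------------------------

def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _sidechain_atoms(system, rid):
    atoms = [int(a) for a in system.residue_atom_indices(rid)]
    side = [a for a in atoms if not system.is_backbone[a]]
    if not side:
        side = [a for a in atoms if system.atom_name[a] == "CA"]
    return side


def _eligible(system, i, j):
    if system.res_chain[i] != system.res_chain[j]:
        return "binding"
    if abs(int(system.res_index[i]) - int(system.res_index[j])) >= MIN_SEQUENCE_SEPARATION:
        return "tertiary"
    return None


def oracle_generic_pairs(coords, system):
    """All residue pairs with min side-chain heavy-atom distance < 6.5 Å."""
    hits = set()
    for i in range(system.n_residues):
        for j in range(i + 1, system.n_residues):
            if _eligible(system, i, j) is None:
                continue
            dmin = min(
                _dist(coords[a], coords[b])
                for a in _sidechain_atoms(system, i)
                for b in _sidechain_atoms(system, j)
            )
            if dmin < CONTACT_CUTOFF:
                hits.add((i, j))
    return hits


def _charge_center(coords, system, rid):
    atoms = [int(a) for a in system.residue_atom_indices(rid)]
    group = CHARGE_GROUP_ATOMS.get(str(system.res_name[rid]), ())
    sel = [a for a in atoms if system.atom_name[a] in group]
    if not sel:
        sel = _sidechain_atoms(system, rid)
    total = sum(system.masses[a] for a in sel)
    return tuple(
        sum(system.masses[a] * coords[a][k] for a in sel) / total for k in range(3)
    )


def oracle_electrostatic_pairs(coords, system):
    hits = set()
    for i in range(system.n_residues):
        for j in range(i + 1, system.n_residues):
            classes = {system.res_class[i], system.res_class[j]}
            if classes != {"positive", "negative"}:
                continue
            if _eligible(system, i, j) is None:
                continue
            d = _dist(_charge_center(coords, system, i), _charge_center(coords, system, j))
            if d < ELECTROSTATIC_CUTOFF:
                hits.add((i, j))
    return hits


def _angle(a, b, c):
    v1 = [x - y for x, y in zip(a, b)]
    v2 = [x - y for x, y in zip(c, b)]
    dot = sum(x * y for x, y in zip(v1, v2))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))


def oracle_hbond_pairs(coords, system):
    def donors(rid):
        atoms = {system.atom_name[a]: int(a) for a in system.residue_atom_indices(rid)}
        out = []
        if str(system.res_name[rid]) != "PRO" and "N" in atoms and "CA" in atoms:
            out.append((atoms["N"], atoms["CA"]))
        for d, ante in _SIDECHAIN_DONORS.get(str(system.res_name[rid]), ()):
            if d in atoms and ante in atoms:
                out.append((atoms[d], atoms[ante]))
        return out

    def acceptors(rid):
        atoms = {system.atom_name[a]: int(a) for a in system.residue_atom_indices(rid)}
        out = [atoms["O"]] if "O" in atoms else []
        out += [
            atoms[n]
            for n in _SIDECHAIN_ACCEPTORS.get(str(system.res_name[rid]), ())
            if n in atoms
        ]
        return out

    hits = set()
    for i in range(system.n_residues):
        for j in range(system.n_residues):
            if i == j or _eligible(system, min(i, j), max(i, j)) is None:
                continue
            for d, ante in donors(i):
                for a in acceptors(j):
                    if (
                        _dist(coords[d], coords[a]) < HBOND_DISTANCE_CUTOFF
                        and _angle(coords[ante], coords[d], coords[a]) > HBOND_ANGLE_CUTOFF
                    ):
                        hits.add((min(i, j), max(i, j)))
    return hits


def oracle_rg(coords, masses=None):
    n = len(coords)
    w = [1.0] * n if masses is None else list(masses)
    total = sum(w)
    centroid = [sum(w[i] * coords[i][k] for i in range(n)) / total for k in range(3)]
    s = sum(w[i] * _dist(coords[i], centroid) ** 2 for i in range(n)) / total
    return math.sqrt(s)


def random_rotation(rng):
    """Uniform-ish random proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
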