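"""Typed residue-residue contacts and native-contact fractions.

Contact rules
-------------
* generic / hydrophobic: two non-adjacent residues are in contact when the
  minimum distance between their side-chain heavy atoms is below 6.5 Å
  (glycine contributes its Cα).  The pair is typed ``hydrophobic`` when both
  residues are hydrophobic, ``generic`` otherwise.
* electrostatic: one residue positive, the other negative, and the distance
  between the centres of mass of the two side-chain charge groups below 11 Å.
* hydrogen bond: donor-acceptor heavy-atom distance below 3.5 Å with an
  antecedent-donor-acceptor angle above 120°.

Intra-chain ("tertiary") contacts require a sequence separation of at least
two residues; all inter-chain pairs are eligible ("binding" contacts).  The
per-frame fractions Qf (native tertiary) and Qb (native binding) drive the
unbinding-kinetics analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .system_model import Ensemble, SystemModel

__all__ = [
    "CONTACT_CUTOFF",
    "ELECTROSTATIC_CUTOFF",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "Contact",
    "ContactSet",
    "QSeries",
    "assign_generic_contacts",
    "assign_electrostatic_contacts",
    "assign_hbonds",
    "native_contacts",
    "q_series",
    "contact_population",
    "min_sidechain_distances",
]

CONTACT_CUTOFF = 6.5  # Å, side-chain heavy-atom minimum distance (strict <)
ELECTROSTATIC_CUTOFF = 11.0  # Å, charge-group centre-of-mass distance
HBOND_DISTANCE_CUTOFF = 3.5  # Å, donor-acceptor heavy atoms
HBOND_ANGLE_CUTOFF = 120.0  # degrees, antecedent-donor-acceptor
MIN_SEQUENCE_SEPARATION = 2  # intra-chain pairs closer in sequence are skipped

# Side-chain charge-group atoms used for the electrostatic rule.  When a
# reduced model lacks these atoms the side-chain heavy atoms stand in.
CHARGE_GROUP_ATOMS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}

# Hydrogen-bond chemistry: donor -> antecedent heavy atom, per residue type.
# The backbone amide N (antecedent CA) donates for every residue but proline;
# the backbone carbonyl O accepts for every residue.
_SIDECHAIN_DONORS = {
    "SER": (("OG", "CB"),),
    "THR": (("OG1", "CB"),),
    "TYR": (("OH", "CZ"),),
    "ASN": (("ND2", "CG"),),
    "GLN": (("NE2", "CD"),),
    "LYS": (("NZ", "CE"),),
    "ARG": (("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")),
    "HIS": (("ND1", "CG"), ("NE2", "CD2")),
    "TRP": (("NE1", "CD1"),),
    "CYS": (("SG", "CB"),),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}


@dataclass(frozen=True, order=True)
class Contact:
    """A typed residue-pair contact (residue ids are internal, i < j)."""

    residue_i: int
    residue_j: int
    kind: str = "generic"  # hydrophobic | electrostatic | hbond | generic
    scope: str = "tertiary"  # tertiary | binding
    native: bool = False

    def __post_init__(self) -> None:
        if self.residue_i >= self.residue_j:
            raise ValueError("contacts require residue_i < residue_j")


@dataclass
class ContactSet:
    """A collection of contacts over one system."""

    system: SystemModel
    contacts: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def tertiary(self) -> list[Contact]:
        return [c for c in self.contacts if c.scope == "tertiary"]

    @property
    def binding(self) -> list[Contact]:
        return [c for c in self.contacts if c.scope == "binding"]

    @property
    def n_native_tertiary(self) -> int:
        return sum(1 for c in self.tertiary if c.native)

    @property
    def n_native_binding(self) -> int:
        return sum(1 for c in self.binding if c.native)

    def for_chain(self, chain: str) -> "ContactSet":
        """Tertiary contacts within one chain plus all binding contacts."""
        keep = []
        for c in self.contacts:
            ci = self.system.res_chain[c.residue_i]
            cj = self.system.res_chain[c.residue_j]
            if c.scope == "binding" or (ci == chain and cj == chain):
                keep.append(c)
        return ContactSet(system=self.system, contacts=keep)


@dataclass
class QSeries:
    """Native-contact fractions per frame.

    ``qf``/``qb`` are ``None`` (undefined, not zero) when the system has no
    native contacts of the corresponding scope.
    """

    times: np.ndarray
    qf: np.ndarray | None
    qb: np.ndarray | None
    n_native_tertiary: int
    n_native_binding: int

    def channel(self, name: str) -> np.ndarray:
        value = {"qf": self.qf, "qb": self.qb}[name]
        if value is None:
            raise ValueError(f"channel {name} is undefined (no native contacts)")
        return value


def _scope_of(system: SystemModel, i: int, j: int) -> str | None:
    """Contact scope for a residue pair, or None if the pair is ineligible."""
    if system.res_chain[i] != system.res_chain[j]:
        return "binding"
    if abs(int(system.res_index[i]) - int(system.res_index[j])) >= MIN_SEQUENCE_SEPARATION:
        return "tertiary"
    return None


def min_sidechain_distances(coords: np.ndarray, system: SystemModel) -> np.ndarray:
    """(n_res, n_res) matrix of minimum side-chain heavy-atom distances."""
    sc_atoms: list[int] = []
    sc_owner: list[int] = []
    for rid in range(system.n_residues):
        for a in system.side_chain_heavy_atoms(rid):
            sc_atoms.append(int(a))
            sc_owner.append(rid)
    idx = np.asarray(sc_atoms, dtype=int)
    owner = np.asarray(sc_owner, dtype=int)
    dist = cdist(coords[idx], coords[idx])
    n = system.n_residues
    out = np.full((n, n), np.inf)
    np.minimum.at(out, (owner[:, None], owner[None, :]), dist)
    return out


def assign_generic_contacts(
    coords: np.ndarray, system: SystemModel, native: bool = False
) -> ContactSet:
    """All residue pairs satisfying the 6.5 Å side-chain rule."""
    mind = min_sidechain_distances(np.asarray(coords, dtype=float), system)
    contacts = []
    n = system.n_residues
    for i in range(n):
        for j in range(i + 1, n):
            if mind[i, j] >= CONTACT_CUTOFF:
                continue
            scope = _scope_of(system, i, j)
            if scope is None:
                continue
            both_hydrophobic = (
                system.res_class[i] == "hydrophobic"
                and system.res_class[j] == "hydrophobic"
            )
            contacts.append(
                Contact(i, j, "hydrophobic" if both_hydrophobic else "generic",
                        scope, native)
            )
    return ContactSet(system=system, contacts=contacts)


def _charge_center(coords: np.ndarray, system: SystemModel, rid: int) -> np.ndarray:
    atoms = system.residue_atom_indices(rid)
    names = set(system.atom_name[atoms])
    group = CHARGE_GROUP_ATOMS.get(str(system.res_name[rid]), ())
    sel = [a for a in atoms if system.atom_name[a] in group]
    if not sel or not names.intersection(group):
        sel = list(system.side_chain_heavy_atoms(rid))
    sel = np.asarray(sel, dtype=int)
    w = system.masses[sel]
    return np.average(coords[sel], axis=0, weights=w)


def assign_electrostatic_contacts(
    coords: np.ndarray, system: SystemModel, native: bool = False
) -> ContactSet:
    """Oppositely charged residue pairs with charge centres below 11 Å."""
    coords = np.asarray(coords, dtype=float)
    pos = np.flatnonzero(system.res_class == "positive")
    neg = np.flatnonzero(system.res_class == "negative")
    centers = {int(r): _charge_center(coords, system, int(r))
               for r in np.concatenate([pos, neg])} if (pos.size and neg.size) else {}
    contacts = []
    for p in pos:
        for q in neg:
            i, j = (int(p), int(q)) if p < q else (int(q), int(p))
            scope = _scope_of(system, i, j)
            if scope is None:
                continue
            d = np.linalg.norm(centers[int(p)] - centers[int(q)])
            if d < ELECTROSTATIC_CUTOFF:
                contacts.append(Contact(i, j, "electrostatic", scope, native))
    return ContactSet(system=system, contacts=sorted(contacts))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_atoms(system: SystemModel, rid: int) -> list[tuple[int, int]]:
    """(donor, antecedent) atom-index pairs present in this residue."""
    atoms = system.residue_atom_indices(rid)
    by_name = {system.atom_name[a]: int(a) for a in atoms}
    pairs = []
    resname = str(system.res_name[rid])
    if resname != "PRO" and "N" in by_name and "CA" in by_name:
        pairs.append((by_name["N"], by_name["CA"]))
    for donor, antecedent in _SIDECHAIN_DONORS.get(resname, ()):
        if donor in by_name and antecedent in by_name:
            pairs.append((by_name[donor], by_name[antecedent]))
    return pairs


def _acceptor_atoms(system: SystemModel, rid: int) -> list[int]:
    atoms = system.residue_atom_indices(rid)
    by_name = {system.atom_name[a]: int(a) for a in atoms}
    accept = []
    if "O" in by_name:
        accept.append(by_name["O"])
    for name in _SIDECHAIN_ACCEPTORS.get(str(system.res_name[rid]), ()):
        if name in by_name:
            accept.append(by_name[name])
    return accept


def assign_hbonds(
    coords: np.ndarray, system: SystemModel, native: bool = False
) -> ContactSet:
    """Residue pairs linked by at least one donor-acceptor hydrogen bond."""
    coords = np.asarray(coords, dtype=float)
    donors = {r: _donor_atoms(system, r) for r in range(system.n_residues)}
    acceptors = {r: _acceptor_atoms(system, r) for r in range(system.n_residues)}
    found: set[Contact] = set()
    n = system.n_residues
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = (i, j) if i < j else (j, i)
            scope = _scope_of(system, lo, hi)
            if scope is None:
                continue
            hit = False
            for d, ante in donors[i]:
                for a in acceptors[j]:
                    if np.linalg.norm(coords[d] - coords[a]) >= HBOND_DISTANCE_CUTOFF:
                        continue
                    if _angle_deg(coords[ante], coords[d], coords[a]) > HBOND_ANGLE_CUTOFF:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                found.add(Contact(lo, hi, "hbond", scope, native))
    return ContactSet(system=system, contacts=sorted(found))


def native_contacts(reference_coords: np.ndarray, system: SystemModel) -> ContactSet:
    """Native contact set: the generic 6.5 Å contacts of the reference
    structure, partitioned into tertiary/binding scope and flagged native."""
    return assign_generic_contacts(reference_coords, system, native=True)


def q_series(ensemble: Ensemble, native: ContactSet, chain: str | None = None) -> QSeries:
    """Per-frame fractions of native tertiary (Qf) and binding (Qb) contacts.

    A native contact counts as satisfied in a frame when the generic 6.5 Å
    side-chain criterion holds there.  With ``chain`` given, Qf is restricted
    to that chain's tertiary contacts (Qb always pools all binding contacts);
    by default tertiary contacts of both chains are pooled.
    """
    contact_set = native.for_chain(chain) if chain is not None else native
    tert = [c for c in contact_set.tertiary if c.native]
    bind = [c for c in contact_set.binding if c.native]
    tert_pairs = np.array([(c.residue_i, c.residue_j) for c in tert], dtype=int)
    bind_pairs = np.array([(c.residue_i, c.residue_j) for c in bind], dtype=int)
    n_frames = ensemble.n_frames
    qf = np.empty(n_frames) if len(tert) else None
    qb = np.empty(n_frames) if len(bind) else None
    for f in range(n_frames):
        mind = min_sidechain_distances(ensemble.frames[f], ensemble.system)
        if qf is not None:
            qf[f] = np.mean(mind[tert_pairs[:, 0], tert_pairs[:, 1]] < CONTACT_CUTOFF)
        if qb is not None:
            qb[f] = np.mean(mind[bind_pairs[:, 0], bind_pairs[:, 1]] < CONTACT_CUTOFF)
    return QSeries(
        times=ensemble.times.copy(),
        qf=qf,
        qb=qb,
        n_native_tertiary=len(tert),
        n_native_binding=len(bind),
    )


def contact_satisfied(coords: np.ndarray, system: SystemModel, contact: Contact) -> bool:
    """Does the contact's own geometric criterion hold in this frame?"""
    coords = np.asarray(coords, dtype=float)
    i, j = contact.residue_i, contact.residue_j
    if contact.kind == "electrostatic":
        d = np.linalg.norm(
            _charge_center(coords, system, i) - _charge_center(coords, system, j)
        )
        return bool(d < ELECTROSTATIC_CUTOFF)
    if contact.kind == "hbond":
        for di, dj in ((i, j), (j, i)):
            for d, ante in _donor_atoms(system, di):
                for a in _acceptor_atoms(system, dj):
                    if (
                        np.linalg.norm(coords[d] - coords[a]) < HBOND_DISTANCE_CUTOFF
                        and _angle_deg(coords[ante], coords[d], coords[a])
                        > HBOND_ANGLE_CUTOFF
                    ):
                        return True
        return False
    ai = system.side_chain_heavy_atoms(i)
    aj = system.side_chain_heavy_atoms(j)
    return bool(cdist(coords[ai], coords[aj]).min() < CONTACT_CUTOFF)


def contact_population(ensemble: Ensemble, contact: Contact) -> float:
    """Fraction of frames in which the contact criterion holds."""
    hits = sum(
        contact_satisfied(ensemble.frames[f], ensemble.system, contact)
        for f in range(ensemble.n_frames)
    )
    return hits / ensemble.n_frames
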