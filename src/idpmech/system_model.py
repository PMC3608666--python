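"""Structural data model: topology, ensembles, superposition and size/deviation primitives.

Coordinates are in Angstrom and timestamps in picoseconds throughout the
package.  A :class:`SystemModel` holds the two-chain topology (atoms, residues,
physico-chemical residue classes, masses) together with the reference
coordinates; an :class:`Ensemble` is an ordered stack of frames over that
topology.  The module also provides the rigid-body primitives every later
stage builds on: Kabsch superposition, RMSD and radius of gyration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "SystemModel",
    "Ensemble",
    "Superposition",
    "PDBFormatError",
    "HYDROPHOBIC_RESIDUES",
    "POSITIVE_RESIDUES",
    "NEGATIVE_RESIDUES",
    "classify_residue",
    "read_pdb",
    "write_pdb",
    "write_coordinate_table",
    "read_coordinate_table",
    "superpose",
    "rmsd",
    "pairwise_rmsd",
    "radius_of_gyration",
]

# Residue classes used by the contact rules.  ALA and PRO count as
# hydrophobic so that contacts such as Ala/Pro interface pairs are typed
# hydrophobic; HIS is grouped with the positively charged residues.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "MET", "PHE", "TRP", "CYS"}
)
POSITIVE_RESIDUES = frozenset({"ARG", "LYS", "HIS"})
NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "TIP", "TIP3", "SOL"})


class PDBFormatError(ValueError):
    """Raised for malformed or structurally inconsistent PDB input."""


def classify_residue(name: str) -> str:
    """Map a 3-letter residue name to its class.

    Returns one of ``hydrophobic``, ``positive``, ``negative`` or ``other``.
    """
    name = name.upper()
    if name in HYDROPHOBIC_RESIDUES:
        return "hydrophobic"
    if name in POSITIVE_RESIDUES:
        return "positive"
    if name in NEGATIVE_RESIDUES:
        return "negative"
    return "other"


@dataclass
class SystemModel:
    """Two-chain topology plus reference coordinates.

    Residues and atoms are stored as parallel numpy arrays; ``atom_res[i]``
    indexes into the residue arrays.  Residue numbering from the input file
    is preserved verbatim in ``res_index`` (no renumbering), while internal
    residue ids are simply positions in the residue arrays.
    """

    chains: list[str]
    res_chain: np.ndarray  # (n_res,) str
    res_index: np.ndarray  # (n_res,) int, input numbering
    res_name: np.ndarray  # (n_res,) str
    res_class: np.ndarray  # (n_res,) str
    atom_res: np.ndarray  # (n_atoms,) int -> residue id
    atom_name: np.ndarray  # (n_atoms,) str
    element: np.ndarray  # (n_atoms,) str
    masses: np.ndarray  # (n_atoms,) float, Da
    is_backbone: np.ndarray  # (n_atoms,) bool
    reference_coords: np.ndarray  # (n_atoms, 3) float, Angstrom

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.shape != (self.n_atoms, 3):
            raise ValueError("reference_coords must be (n_atoms, 3)")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        if self.atom_res.min(initial=0) < 0 or (
            self.n_atoms and self.atom_res.max() >= self.n_residues
        ):
            raise ValueError("atom_res indexes outside the residue table")
        for chain in self.chains:
            idx = self.res_index[self.res_chain == chain]
            if idx.size and np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"residue indices must be strictly increasing in chain {chain}"
                )

    # -- sizes ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_residues(self) -> int:
        return len(self.res_name)

    # -- selections ----------------------------------------------------
    def ca_indices(self, chain: str | None = None) -> np.ndarray:
        """Atom indices of Cα atoms, optionally restricted to one chain."""
        mask = self.atom_name == "CA"
        if chain is not None:
            mask &= self.res_chain[self.atom_res] == chain
        return np.flatnonzero(mask)

    def chain_atom_indices(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.res_chain[self.atom_res] == chain)

    def chain_residue_ids(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.res_chain == chain)

    def residue_atom_indices(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.atom_res == res_id)

    def side_chain_heavy_atoms(self, res_id: int) -> np.ndarray:
        """Heavy side-chain atom indices of one residue.

        For glycine (no side chain) the Cα substitutes.  Hydrogens are
        already absent from the model.
        """
        atoms = self.residue_atom_indices(res_id)
        side = atoms[~self.is_backbone[atoms]]
        if side.size == 0:
            side = atoms[self.atom_name[atoms] == "CA"]
        return side

    def residue_label(self, res_id: int) -> str:
        return (
            f"{self.res_name[res_id]}{self.res_index[res_id]}"
            f".{self.res_chain[res_id]}"
        )

    def subset(self, atom_indices: np.ndarray) -> tuple["SystemModel", np.ndarray]:
        """Restrict the model to a set of atoms (e.g. one chain).

        Returns the sub-model and the atom index array (in original order)
        so that ensembles can be sliced consistently.
        """
        atom_indices = np.asarray(atom_indices, dtype=int)
        res_ids = np.unique(self.atom_res[atom_indices])
        res_remap = {old: new for new, old in enumerate(res_ids)}
        chains = [c for c in self.chains if c in set(self.res_chain[res_ids])]
        return (
            SystemModel(
                chains=chains,
                res_chain=self.res_chain[res_ids].copy(),
                res_index=self.res_index[res_ids].copy(),
                res_name=self.res_name[res_ids].copy(),
                res_class=self.res_class[res_ids].copy(),
                atom_res=np.array(
                    [res_remap[r] for r in self.atom_res[atom_indices]], dtype=int
                ),
                atom_name=self.atom_name[atom_indices].copy(),
                element=self.element[atom_indices].copy(),
                masses=self.masses[atom_indices].copy(),
                is_backbone=self.is_backbone[atom_indices].copy(),
                reference_coords=self.reference_coords[atom_indices].copy(),
            ),
            atom_indices,
        )


@dataclass
class Ensemble:
    """Ordered conformational frames with timestamps for one system state."""

    system: SystemModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ps, strictly increasing
    label: str = "bound"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != system atom "
                f"count {self.system.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must align with frames")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def select_atoms(self, atom_indices: np.ndarray, system: SystemModel) -> "Ensemble":
        return Ensemble(
            system=system,
            frames=self.frames[:, np.asarray(atom_indices, dtype=int), :].copy(),
            times=self.times.copy(),
            label=self.label,
        )

    def extract_chain(self, chain: str) -> "Ensemble":
        """Single-chain view of a multi-chain ensemble."""
        sub, idx = self.system.subset(self.system.chain_atom_indices(chain))
        return self.select_atoms(idx, sub)

    def slice_frames(self, frame_indices: np.ndarray) -> "Ensemble":
        frame_indices = np.asarray(frame_indices, dtype=int)
        return Ensemble(
            system=self.system,
            frames=self.frames[frame_indices].copy(),
            times=self.times[frame_indices].copy(),
            label=self.label,
        )


@dataclass
class Superposition:
    """Rigid-body (rotation + translation) least-squares fit."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom, over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform coordinates into the target frame."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ----------------------------------------------------------------------
# PDB and coordinate-table input/output
# ----------------------------------------------------------------------

def _validate_atom_records(path: str) -> None:
    """Light well-formedness scan so parse errors can name the line."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: truncated ATOM record"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path}:{lineno}: unparseable coordinates in ATOM record"
                ) from exc


def _element_of(atom) -> str:
    elem = (atom.element or "").strip().capitalize()
    if not elem:
        name = atom.get_name().strip()
        elem = next((c for c in name if c.isalpha()), "C").capitalize()
    return elem


def read_pdb(
    path: str,
    model_policy: str = "all_models",
    dt: float = 1.0,
    expected_chains: int | None = None,
) -> tuple[SystemModel, Ensemble]:
    """Read a (multi-model) PDB file into a system model and an ensemble.

    Waters, other heteroatoms and hydrogens are dropped; for disordered
    atoms the highest-occupancy conformer is kept (Biopython's default
    selection).  Each MODEL becomes one frame; timestamps default to
    ``frame_index * dt`` picoseconds.

    Parameters
    ----------
    model_policy:
        ``"first_model"`` keeps only the first MODEL, ``"all_models"``
        keeps every MODEL as a frame.
    dt:
        Frame spacing in ps used to synthesise timestamps.
    expected_chains:
        If given, raise when the file does not contain this many chains.
    """
    if model_policy not in ("first_model", "all_models"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    _validate_atom_records(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("system", path)
    except PDBConstructionException as exc:  # pragma: no cover - biopython detail
        raise PDBFormatError(f"{path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise PDBFormatError(f"{path}: no MODEL/coordinate content")
    if model_policy == "first_model":
        models = models[:1]

    first = models[0]
    res_chain, res_index, res_name = [], [], []
    atom_res, atom_name, element, masses, backbone = [], [], [], [], []
    coords0 = []
    atom_keys = []  # (chain, resid, atomname) for cross-model lookup
    chains = []
    for chain in first:
        residues_seen = False
        for residue in chain:
            hetflag = residue.get_id()[0]
            if hetflag != " " or residue.get_resname().strip() in _WATER_NAMES:
                continue
            residues_seen = True
            rid = len(res_name)
            res_chain.append(chain.id)
            res_index.append(residue.get_id()[1])
            res_name.append(residue.get_resname().strip())
            for atom in residue:
                elem = _element_of(atom)
                if elem == "H":
                    continue
                atom_res.append(rid)
                name = atom.get_name().strip()
                atom_name.append(name)
                element.append(elem)
                masses.append(atom_weights.get(elem, 12.011))
                backbone.append(name in BACKBONE_ATOMS)
                coords0.append(atom.get_coord())
                atom_keys.append((chain.id, residue.get_id(), name))
        if residues_seen:
            chains.append(chain.id)

    if not atom_keys:
        raise PDBFormatError(f"{path}: no protein ATOM records")
    if expected_chains is not None and len(chains) != expected_chains:
        raise PDBFormatError(
            f"{path}: expected {expected_chains} chains, found {len(chains)}"
        )

    system = SystemModel(
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
        reference_coords=np.array(coords0, dtype=float),
    )

    frames = np.empty((len(models), system.n_atoms, 3), dtype=float)
    frames[0] = system.reference_coords
    for f, model in enumerate(models[1:], start=1):
        for a, (chain_id, res_id, name) in enumerate(atom_keys):
            try:
                frames[f, a] = model[chain_id][res_id][name].get_coord()
            except KeyError as exc:
                raise PDBFormatError(
                    f"{path}: MODEL {f + 1} is missing atom "
                    f"{name} of {chain_id}/{res_id[1]}"
                ) from exc
    times = np.arange(len(models), dtype=float) * dt
    ensemble = Ensemble(system=system, frames=frames, times=times, label="bound")
    return system, ensemble


def write_pdb(path: str, system: SystemModel, frames: np.ndarray | None = None) -> None:
    """Write the system (optionally multi-frame) as a multi-model PDB file."""
    if frames is None:
        frames = system.reference_coords[None]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    multi = frames.shape[0] > 1
    with open(path, "w") as out:
        for f in range(frames.shape[0]):
            if multi:
                out.write(f"MODEL     {f + 1:4d}\n")
            serial = 0
            for a in range(system.n_atoms):
                serial += 1
                rid = system.atom_res[a]
                name = system.atom_name[a]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = frames[f, a]
                out.write(
                    f"ATOM  {serial:5d} {pdb_name:<4s} "
                    f"{system.res_name[rid]:<3s} {system.res_chain[rid]}"
                    f"{system.res_index[rid]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {system.element[a]:>2s}\n"
                )
            out.write("TER\n")
            if multi:
                out.write("ENDMDL\n")
        out.write("END\n")


def write_coordinate_table(path: str, ensemble: Ensemble) -> None:
    """Write the plain-text interchange table (one row per atom per frame)."""
    system = ensemble.system
    with open(path, "w") as out:
        out.write("frame\ttime_ps\tchain\tresid\tresname\tatom\tx\ty\tz\n")
        for f in range(ensemble.n_frames):
            t = ensemble.times[f]
            for a in range(system.n_atoms):
                rid = system.atom_res[a]
                x, y, z = ensemble.frames[f, a]
                out.write(
                    f"{f}\t{t:.4f}\t{system.res_chain[rid]}\t"
                    f"{system.res_index[rid]}\t{system.res_name[rid]}\t"
                    f"{system.atom_name[a]}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n"
                )


def read_coordinate_table(path: str, system: SystemModel, label: str = "bound") -> Ensemble:
    """Read the plain-text interchange table back into an ensemble."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    n_frames = table["frame"].nunique()
    frames = np.empty((n_frames, system.n_atoms, 3), dtype=float)
    times = np.empty(n_frames, dtype=float)
    for f, (frame_no, group) in enumerate(table.groupby("frame", sort=True)):
        if len(group) != system.n_atoms:
            raise ValueError(
                f"frame {frame_no} has {len(group)} atoms, expected {system.n_atoms}"
            )
        frames[f] = group[["x", "y", "z"]].to_numpy()
        times[f] = group["time_ps"].iloc[0]
    return Ensemble(system=system, frames=frames, times=times, label=label)


# ----------------------------------------------------------------------
# Rigid-body primitives
# ----------------------------------------------------------------------

def _check_selection(n_atoms: int, selection: np.ndarray | None) -> np.ndarray:
    if selection is None:
        selection = np.arange(n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    return selection


def superpose(
    mobile_coords: np.ndarray,
    target_coords: np.ndarray,
    atom_selection: np.ndarray | None = None,
) -> Superposition:
    """Least-squares rigid-body fit of mobile onto target (Kabsch).

    The returned transform minimises the RMSD over the selection; the
    rotation is a proper rotation (det = +1, reflections are sign-corrected
    away).  Applying the transform to the full mobile coordinates yields the
    fitted coordinates.
    """
    mobile_coords = np.asarray(mobile_coords, dtype=float)
    target_coords = np.asarray(target_coords, dtype=float)
    if mobile_coords.shape != target_coords.shape:
        raise ValueError("mobile and target must cover the same atoms")
    sel = _check_selection(mobile_coords.shape[0], atom_selection)
    x = mobile_coords[sel]
    y = target_coords[sel]
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise ValueError("degenerate fit: selected atoms are (nearly) collinear")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc
    fitted = x0 @ rotation.T
    value = float(np.sqrt(np.mean(np.sum((fitted - y0) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation, rmsd=value)


def rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    atom_selection: np.ndarray | None = None,
    fit: bool = False,
) -> float:
    """Root-mean-square deviation over a selection, optionally after fitting."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.shape != coords_b.shape:
        raise ValueError("coordinate arrays must match in shape")
    sel = _check_selection(coords_a.shape[0], atom_selection)
    if fit:
        return superpose(coords_a, coords_b, sel).rmsd
    diff = coords_a[sel] - coords_b[sel]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def pairwise_rmsd(frames: np.ndarray, fit: bool = True) -> np.ndarray:
    """All-pairs RMSD between frames, vectorised over pairs.

    ``frames`` is (n_frames, n_atoms, 3).  With ``fit`` each pair is
    optimally superposed (batched Kabsch via SVD); the result is a symmetric
    matrix with zero diagonal.
    """
    frames = np.asarray(frames, dtype=float)
    n, m, _ = frames.shape
    out = np.zeros((n, n), dtype=float)
    ii, jj = np.triu_indices(n, k=1)
    if ii.size == 0:
        return out
    if not fit:
        diff = frames[ii] - frames[jj]
        vals = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    else:
        centred = frames - frames.mean(axis=1, keepdims=True)
        sq = np.sum(centred**2, axis=(1, 2))  # (n,)
        h = np.einsum("pai,paj->pij", centred[ii], centred[jj])
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("pij,pjk->pik", vt.transpose(0, 2, 1),
                                      u.transpose(0, 2, 1)))
        s_corr = s.copy()
        s_corr[:, 2] *= np.sign(det)
        msd = (sq[ii] + sq[jj] - 2.0 * s_corr.sum(axis=1)) / m
        vals = np.sqrt(np.clip(msd, 0.0, None))
        # the closed form cancels catastrophically near zero; recompute the
        # few near-identical pairs explicitly
        small = np.flatnonzero(vals < 1e-4)
        for p in small:
            fit = superpose(frames[jj[p]], frames[ii[p]])
            vals[p] = fit.rmsd
    out[ii, jj] = vals
    out[jj, ii] = vals
    return out


def radius_of_gyration(
    coords: np.ndarray,
    atom_selection: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Radius of gyration about the (mass-weighted) centroid, in Angstrom."""
    coords = np.asarray(coords, dtype=float)
    sel = _check_selection(coords.shape[0], atom_selection)
    x = coords[sel]
    if masses is None:
        w = np.ones(sel.size)
    else:
        w = np.asarray(masses, dtype=float)[sel]
    w = w / w.sum()
    centroid = np.average(x, axis=0, weights=w)
    return float(np.sqrt(np.sum(w * np.sum((x - centroid) ** 2, axis=1))))
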