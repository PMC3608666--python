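"""Seeded synthetic systems and ensembles with planted statistical structure.

Real inputs to this kind of analysis are MD ensembles of a two-chain
complex and of each apo chain.  The generators here build a reduced toy
complex (ideal helix/coil backbone, one side-chain pseudo-atom per residue
carrying the residue's side-chain mass) and plant the statistical features
each pipeline stage estimates:

* bound/apo ensemble pairs whose deviation structure encodes a known
  conformational-selection / induced-fit mechanism,
* unfolding trajectories whose native-contact fraction decays
  exponentially with a known rate,
* trajectories dwelling sequentially in k conformational basins with
  recorded switch frames.

Everything is deterministic under a fixed seed.  There is no force field
and no thermodynamics here — statistical structure only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contacts import ContactSet, assign_generic_contacts, native_contacts
from .contacts import QSeries
from .csif import LOCAL_CUTOFF
from .system_model import Ensemble, SystemModel, classify_residue
from .transition_state import ClusterSegmentation

__all__ = [
    "SyntheticSpec",
    "build_peptide",
    "build_study_complex",
    "build_toy_complex",
    "sample_csif_ensembles",
    "sample_unfolding_trajectory",
    "sample_clustered_trajectory",
    "synth_q_series",
]

# Side-chain heavy-atom masses (Da) carried by the single pseudo-atom.
SIDECHAIN_MASS = {
    "ALA": 15.0, "VAL": 43.1, "LEU": 57.1, "ILE": 57.1, "PRO": 42.1,
    "MET": 75.1, "PHE": 91.1, "TRP": 130.2, "CYS": 47.1, "ARG": 101.1,
    "LYS": 73.1, "HIS": 82.1, "ASP": 59.0, "GLU": 73.1, "SER": 31.0,
    "THR": 45.1, "ASN": 58.1, "GLN": 72.1, "TYR": 107.1, "GLY": 0.0,
}

_COMPOSITION = {
    "ALA": 8, "VAL": 6, "LEU": 9, "ILE": 5, "PRO": 5, "MET": 3, "PHE": 4,
    "TRP": 2, "CYS": 1, "ARG": 5, "LYS": 6, "HIS": 2, "ASP": 6, "GLU": 7,
    "SER": 7, "THR": 6, "ASN": 4, "GLN": 4, "GLY": 7, "TYR": 3,
}

HELIX_PHI, HELIX_PSI = -57.0, -47.0  # canonical alpha-helix


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study system.

    The defaults emulate the study conditions the package is built for: a
    ~58-residue three-helix chain bound to a ~54-residue two-helix chain,
    ensembles of 50 frames spanning 10 ns, unfolding on the nanosecond
    scale, and a three-basin high-temperature trajectory sampled every
    20 ps.
    """

    seed: int = 0
    chain_lengths: tuple[int, int] = (58, 54)
    helix_segments: tuple[tuple[tuple[int, int], ...], ...] = (
        ((7, 16), (22, 33), (36, 46)),
        ((7, 13), (35, 41)),
    )
    min_binding_contacts: int = 5
    # bound/apo ensembles for the CS/IF analysis
    n_frames: int = 50
    frame_interval_ps: float = 200.0
    amplitude_near: float = 1.5  # Å, per-coordinate SD of local deformations
    amplitude_far: float = 1.5  # Å, per-coordinate SD of global deformations
    crossover: float = 12.0  # Å from the partner centroid: local vs global
    base_noise: float = 0.2  # Å, per-coordinate thermal jitter
    # unfolding trajectories
    break_rate: float = 2.4e-4  # ps^-1 per native contact (t_1/2 ~ 2.9 ns)
    unfold_frame_interval_ps: float = 20.0
    unfold_n_frames: int = 500
    # clustered (multi-basin) trajectories
    cluster_k: int = 3
    cluster_separation: float = 2.5  # Å, Cα RMSD between basin centres
    cluster_within_sd: float = 0.5  # Å, frame-to-centre Cα RMSD within a basin
    cluster_n_frames: int = 120
    cluster_frame_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude_near < 0 or self.amplitude_far < 0 or self.base_noise < 0:
            raise ValueError("deviation amplitudes must be non-negative")
        if self.break_rate < 0:
            raise ValueError("break rate must be non-negative")
        if self.cluster_k < 1:
            raise ValueError("cluster model needs k >= 1")


# ----------------------------------------------------------------------
# Reduced-backbone geometry
# ----------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of a new atom bonded to c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(-torsion_deg)  # right-handed measured dihedral
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _chain_geometry(
    seq: list[str], phi: np.ndarray, psi: np.ndarray
) -> tuple[np.ndarray, list[list[str]]]:
    """Backbone + side-chain pseudo-atom coordinates from torsions."""
    length = len(seq)
    n_xyz = np.zeros((length, 3))
    ca_xyz = np.zeros((length, 3))
    c_xyz = np.zeros((length, 3))
    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (1.458, 0.0, 0.0)
    ang = np.radians(111.2)
    c_xyz[0] = ca_xyz[0] + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(length - 1):
        n_xyz[i + 1] = _place_atom(
            n_xyz[i], ca_xyz[i], c_xyz[i], 1.329, 116.2, psi[i]
        )
        ca_xyz[i + 1] = _place_atom(
            ca_xyz[i], c_xyz[i], n_xyz[i + 1], 1.458, 121.7, 180.0
        )
        c_xyz[i + 1] = _place_atom(
            c_xyz[i], n_xyz[i + 1], ca_xyz[i + 1], 1.525, 111.2, phi[i + 1]
        )

    coords: list[np.ndarray] = []
    atom_names: list[list[str]] = []
    for i in range(length):
        res_atoms = ["N", "CA", "C", "O"]
        o = _place_atom(n_xyz[i], ca_xyz[i], c_xyz[i], 1.231, 120.8, psi[i] + 180.0)
        row = [n_xyz[i], ca_xyz[i], c_xyz[i], o]
        if seq[i] != "GLY":
            cb = _place_atom(n_xyz[i], c_xyz[i], ca_xyz[i], 2.2, 115.0, 122.6)
            row.append(cb)
            res_atoms.append("CB")
        coords.extend(row)
        atom_names.append(res_atoms)
    return np.asarray(coords), atom_names


def _build_chain(
    length: int,
    helix_segments: tuple[tuple[int, int], ...],
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, list[list[str]]]:
    """Random-sequence chain: ideal helices in the given segments, coil
    elsewhere.  Coil torsions span the broad allowed region (alpha and beta
    basins), which keeps the chains compact and molten-globule-like rather
    than fully extended."""
    names = list(_COMPOSITION)
    weights = np.array([_COMPOSITION[n] for n in names], dtype=float)
    weights /= weights.sum()
    seq = [str(n) for n in rng.choice(names, size=length, p=weights)]

    in_helix = np.zeros(length, dtype=bool)
    for lo, hi in helix_segments:
        in_helix[lo : hi + 1] = True
    phi = np.where(in_helix, HELIX_PHI, rng.uniform(-160.0, -50.0, size=length))
    psi = np.where(in_helix, HELIX_PSI, rng.uniform(-70.0, 170.0, size=length))
    coords, atom_names = _chain_geometry(seq, phi, psi)
    return seq, coords, atom_names


def build_peptide(
    seq: list[str],
    phi: np.ndarray,
    psi: np.ndarray,
    chain: str = "A",
) -> SystemModel:
    """Single-chain reduced peptide built from explicit backbone torsions.

    Useful for constructing ensembles with known dihedral statistics; the
    torsion of residue i is realised exactly (up to float precision) for
    internal residues.
    """
    coords, atom_names = _chain_geometry(list(seq), np.asarray(phi, float),
                                         np.asarray(psi, float))
    return _assemble_system([list(seq)], [coords], [atom_names], [chain])


def _assemble_system(
    seqs: list[list[str]],
    coords: list[np.ndarray],
    atom_names: list[list[list[str]]],
    chains: list[str],
) -> SystemModel:
    res_chain, res_index, res_name = [], [], []
    atom_res, a_name, element, masses, backbone = [], [], [], [], []
    xyz = []
    base_mass = {"N": 14.007, "CA": 13.019, "C": 12.011, "O": 15.999}
    resid0 = 0
    for ci, chain in enumerate(chains):
        for i, resname in enumerate(seqs[ci]):
            rid = len(res_name)
            res_chain.append(chain)
            res_index.append(resid0 + i + 1)
            res_name.append(resname)
            for name in atom_names[ci][i]:
                atom_res.append(rid)
                a_name.append(name)
                if name == "CB":
                    element.append("C")
                    masses.append(max(SIDECHAIN_MASS[resname], 12.011))
                else:
                    element.append("N" if name == "N" else "O" if name == "O" else "C")
                    masses.append(base_mass[name])
                backbone.append(name in ("N", "CA", "C", "O"))
        resid0 += len(seqs[ci])
        xyz.append(coords[ci])
    return SystemModel(
        chains=list(chains),
        res_chain=np.array(res_chain, dtype=object),
        res_index=np.array(res_index, dtype=int),
        res_name=np.array(res_name, dtype=object),
        res_class=np.array([classify_residue(n) for n in res_name], dtype=object),
        atom_res=np.array(atom_res, dtype=int),
        atom_name=np.array(a_name, dtype=object),
        element=np.array(element, dtype=object),
        masses=np.array(masses, dtype=float),
        is_backbone=np.array(backbone, dtype=bool),
        reference_coords=np.vstack(xyz),
    )


def _principal_align(coords: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis of the cloud lies along z, centred."""
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt  # rows are principal directions
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    aligned = centred @ rot.T
    return aligned[:, [1, 2, 0]]  # principal axis -> z


def build_toy_complex(
    spec: SyntheticSpec,
    chain_offset: float | None = None,
) -> tuple[SystemModel, Ensemble]:
    """Build the reduced two-chain complex and its reference ensemble.

    The chains are aligned side by side and chain B is moved toward chain A
    until at least ``spec.min_binding_contacts`` inter-chain residue pairs
    satisfy the 6.5 Å rule without steric clash (minimum inter-chain atom
    distance >= 2.5 Å).  ``chain_offset`` forces a fixed inter-chain offset
    in Å instead of searching (useful to build separated chains).
    """
    rng = np.random.default_rng(spec.seed)
    chains = ["A", "B"]
    seqs, coords, names = [], [], []
    for ci in range(2):
        seq, xyz, atom_names = _build_chain(
            spec.chain_lengths[ci], spec.helix_segments[ci], rng
        )
        seqs.append(seq)
        coords.append(_principal_align(xyz))
        names.append(atom_names)
    system = _assemble_system(seqs, coords, names, chains)
    n_a = coords[0].shape[0]

    def placed(offset: float, angle_deg: float, z_shift: float = 0.0) -> np.ndarray:
        t = np.radians(angle_deg)
        rot = np.array(
            [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
        )
        moved = coords[1] @ rot.T
        moved[:, 0] += offset
        moved[:, 2] += z_shift
        out = system.reference_coords.copy()
        out[n_a:] = moved
        return out

    if chain_offset is not None:
        system.reference_coords = placed(chain_offset, 0.0)
    else:
        # for each trial rotation of B, pack the chains as closely as
        # sterics allow (min inter-chain atom distance >= 2.5 Å), then pick
        # the rotation with the best-buried interface: most analyzed-chain
        # atoms near the partner centroid, subject to enough binding contacts
        best = None
        coarse = [
            (angle, z_shift)
            for angle in np.arange(0.0, 360.0, 30.0)
            for z_shift in (-12.0, -6.0, 0.0, 6.0, 12.0)
        ]
        fine = [
            (angle, z_shift)
            for angle in np.arange(15.0, 360.0, 30.0)
            for z_shift in (-9.0, -3.0, 3.0, 9.0)
        ]
        for angle, z_shift in coarse + fine:
            # a placement that already buries a decent interface is enough
            if best is not None and best[0] >= 10 and (angle, z_shift) in fine:
                break
            packed = None
            for offset in np.arange(30.0, 1.9, -0.5):
                ref = placed(offset, angle, z_shift)
                gap = np.min(
                    np.linalg.norm(ref[:n_a, None, :] - ref[None, n_a:, :], axis=2)
                )
                if gap < 2.5:
                    break
                packed = ref
            if packed is None:
                continue
            system.reference_coords = packed
            n_binding = sum(
                1 for c in assign_generic_contacts(packed, system)
                if c.scope == "binding"
            )
            if n_binding < spec.min_binding_contacts:
                continue
            centroid_b = np.average(
                packed[n_a:], axis=0, weights=system.masses[n_a:]
            )
            n_local = int(
                np.sum(np.linalg.norm(packed[:n_a] - centroid_b, axis=1) < spec.crossover)
            )
            if best is None or n_local > best[0]:
                best = (n_local, packed)
        if best is None:
            raise RuntimeError(
                "could not place the chains with enough binding contacts; "
                "adjust chain lengths or min_binding_contacts"
            )
        system.reference_coords = best[1]

    ensemble = Ensemble(
        system=system,
        frames=system.reference_coords[None].copy(),
        times=np.zeros(1),
        label="bound",
    )
    return system, ensemble


def build_study_complex(
    spec: SyntheticSpec,
    min_local_atoms: int = 8,
    max_tries: int = 8,
) -> tuple[SystemModel, Ensemble, SyntheticSpec]:
    """Build a toy complex whose interface supports the local-scope analysis.

    Random chain shapes occasionally pack so that no analyzed-chain atom
    comes near the partner centroid, leaving the "local" scope of the CS/IF
    statistics empty.  This wrapper regenerates the chains with derived
    seeds (``seed``, ``seed + 1000``, ...) until at least
    ``min_local_atoms`` chain-A atoms lie within the crossover distance of
    chain B's centroid.  Deterministic given ``spec.seed``; returns the
    spec variant actually used.
    """
    last_error = None
    for trial in range(max_tries):
        trial_spec = replace(spec, seed=spec.seed + 1000 * trial)
        try:
            system, reference = build_toy_complex(trial_spec)
        except RuntimeError as exc:
            last_error = exc
            continue
        atoms_a = system.chain_atom_indices("A")
        atoms_b = system.chain_atom_indices("B")
        centroid_b = np.average(
            system.reference_coords[atoms_b], axis=0, weights=system.masses[atoms_b]
        )
        d = np.linalg.norm(system.reference_coords[atoms_a] - centroid_b, axis=1)
        if int(np.sum(d < min(LOCAL_CUTOFF, spec.crossover))) >= min_local_atoms:
            return system, reference, trial_spec
    raise RuntimeError(
        f"no usable complex after {max_tries} tries (last error: {last_error})"
    )


# ----------------------------------------------------------------------
# CS/IF ensembles with a planted mechanism
# ----------------------------------------------------------------------

def _partner_distances(system: SystemModel, chain: str, partner: str) -> np.ndarray:
    partner_atoms = system.chain_atom_indices(partner)
    centroid = np.average(
        system.reference_coords[partner_atoms],
        axis=0,
        weights=system.masses[partner_atoms],
    )
    return np.linalg.norm(system.reference_coords - centroid, axis=1)


def sample_csif_ensembles(
    system: SystemModel,
    spec: SyntheticSpec,
    mechanism: str = "mixed",
    chain: str = "A",
) -> tuple[Ensemble, Ensemble, dict]:
    """Bound + apo ensembles with a planted recognition mechanism.

    * ``cs_dominant``: bound frames sample a broad global conformational
      diversity and each bound conformer has a near-identical apo twin
      (large apo spread, small residual): selection.
    * ``if_dominant``: the apo ensemble is tight around the reference while
      bound frames are deformed near the binding interface (atoms within
      ``spec.crossover`` of the partner centroid): induced fit.
    * ``mixed``: the global diversity (beyond the crossover) is shared
      between bound and apo twins, while an extra interface deformation
      exists only in the bound frames — global selection, local induced fit.

    Returns the bound complex ensemble, the apo ensemble of ``chain`` and a
    ground-truth record of the planted amplitudes.
    """
    if mechanism not in ("cs_dominant", "if_dominant", "mixed"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    partner = "B" if chain == "A" else "A"
    rng = np.random.default_rng(spec.seed)
    ref = system.reference_coords
    n_atoms = system.n_atoms
    d = _partner_distances(system, chain, partner)
    local = d < spec.crossover
    chain_atoms = system.chain_atom_indices(chain)

    if mechanism == "cs_dominant":
        g_amp = np.full(n_atoms, spec.amplitude_far)
        l_amp = np.zeros(n_atoms)
    elif mechanism == "if_dominant":
        g_amp = np.zeros(n_atoms)
        l_amp = np.where(local, spec.amplitude_near, 0.0)
    else:  # mixed
        g_amp = np.where(local, 0.0, spec.amplitude_far)
        l_amp = np.where(local, spec.amplitude_near, 0.0)

    frames_bound = np.empty((spec.n_frames, n_atoms, 3))
    frames_apo = np.empty((spec.n_frames, chain_atoms.size, 3))
    for j in range(spec.n_frames):
        shared = g_amp[:, None] * rng.normal(size=(n_atoms, 3))
        private = l_amp[:, None] * rng.normal(size=(n_atoms, 3))
        frames_bound[j] = (
            ref + shared + private
            + spec.base_noise * rng.normal(size=(n_atoms, 3))
        )
        frames_apo[j] = (
            ref[chain_atoms]
            + shared[chain_atoms]
            + spec.base_noise * rng.normal(size=(chain_atoms.size, 3))
        )
    times = np.arange(spec.n_frames) * spec.frame_interval_ps
    sub_system, _ = system.subset(chain_atoms)
    bound = Ensemble(system=system, frames=frames_bound, times=times.copy(), label="bound")
    apo = Ensemble(
        system=sub_system,
        frames=frames_apo,
        times=times.copy(),
        label=f"apo_{chain}",
    )
    truth = {
        "mechanism": mechanism,
        "chain": chain,
        "global_amplitude": float(spec.amplitude_far),
        "local_amplitude": float(spec.amplitude_near),
        "crossover": float(spec.crossover),
        "local_atoms": np.flatnonzero(local[chain_atoms]),
    }
    return bound, apo, truth


# ----------------------------------------------------------------------
# Unfolding trajectories with first-order contact loss
# ----------------------------------------------------------------------

def sample_unfolding_trajectory(
    system: SystemModel,
    spec: SyntheticSpec,
    native: ContactSet | None = None,
    seed: int | None = None,
) -> Ensemble:
    """Markov unfolding trajectory with E[Q(t)] = exp(-k t).

    Each residue independently "melts" with rate k/2 (probability
    ``1 - exp(-k dt / 2)`` per frame); a melted residue is displaced to a
    well-separated coil position (interpolated over one frame), so a native
    contact is geometrically intact exactly while both of its residues are
    unmelted.  Marginally each contact then survives as exp(-k t), i.e. the
    native-contact fraction decays first-order with the planted rate.
    """
    k = spec.break_rate
    dt = spec.unfold_frame_interval_ps
    n_frames = spec.unfold_n_frames
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if native is None:
        native = native_contacts(system.reference_coords, system)
    ref = system.reference_coords
    span = float(np.ptp(ref)) + 100.0
    # coil positions: a jittered line far from the native region, mutually
    # >= 8 Å apart so no broken native contact can geometrically re-form
    coil = np.zeros((system.n_residues, 3))
    coil[:, 0] = span + 8.0 * np.arange(system.n_residues)
    coil += rng.uniform(-0.5, 0.5, size=coil.shape)

    melt_prob = 1.0 - np.exp(-0.5 * k * dt)
    melted = np.zeros(system.n_residues, dtype=bool)
    melt_frame = np.full(system.n_residues, -1, dtype=int)
    frames = np.empty((n_frames, system.n_atoms, 3))
    frames[0] = ref
    for f in range(1, n_frames):
        newly = (~melted) & (rng.random(system.n_residues) < melt_prob)
        melt_frame[newly] = f
        melted |= newly
        xyz = ref.copy()
        for rid in np.flatnonzero(melted):
            atoms = system.residue_atom_indices(rid)
            shift = coil[rid] - ref[atoms].mean(axis=0)
            lam = 1.0 if f > melt_frame[rid] else 0.9
            xyz[atoms] = ref[atoms] + lam * shift
        frames[f] = xyz
    times = np.arange(n_frames) * dt
    return Ensemble(system=system, frames=frames, times=times, label="bound")


# ----------------------------------------------------------------------
# Multi-basin trajectories
# ----------------------------------------------------------------------

def sample_clustered_trajectory(
    system: SystemModel,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[Ensemble, ClusterSegmentation]:
    """Trajectory dwelling sequentially in k conformational basins.

    Basin centres are global deformations of the reference separated by
    ~``cluster_separation`` Å Cα RMSD; within-basin frames scatter with
    frame-to-centre Cα RMSD ~``cluster_within_sd``.  The planted
    segmentation (switch frames, barrier times) is returned alongside.
    """
    if spec.cluster_k < 2 and spec.cluster_n_frames < 1:
        raise ValueError("need k >= 1 and at least one frame")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_atoms = system.n_atoms
    ref = system.reference_coords
    sep_amp = spec.cluster_separation / np.sqrt(6.0)
    within_amp = spec.cluster_within_sd / np.sqrt(3.0)
    centres = [
        ref + sep_amp * rng.normal(size=(n_atoms, 3)) for _ in range(spec.cluster_k)
    ]
    # dwell lengths: equal shares +-20%, deterministic per seed
    base = spec.cluster_n_frames // spec.cluster_k
    dwells = np.maximum(
        3, (base * rng.uniform(0.8, 1.2, size=spec.cluster_k)).astype(int)
    )
    dwells[-1] = spec.cluster_n_frames - int(dwells[:-1].sum())
    if dwells[-1] < 3:
        raise ValueError("cluster_n_frames too small for the requested k")
    frames = np.empty((spec.cluster_n_frames, n_atoms, 3))
    segments = []
    start = 0
    for b, dwell in enumerate(dwells):
        for f in range(start, start + dwell):
            frames[f] = centres[b] + within_amp * rng.normal(size=(n_atoms, 3))
        segments.append((start, start + dwell - 1, b))
        start += dwell
    times = np.arange(spec.cluster_n_frames) * spec.cluster_frame_interval_ps
    barrier_times = [
        float(0.5 * (times[segments[i][1]] + times[segments[i + 1][0]]))
        for i in range(len(segments) - 1)
    ]
    planted = ClusterSegmentation(segments=segments, barrier_times=barrier_times)
    ensemble = Ensemble(system=system, frames=frames, times=times, label="bound")
    return ensemble, planted


# ----------------------------------------------------------------------
# Direct Q-series synthesis (no geometry)
# ----------------------------------------------------------------------

def synth_q_series(
    rate: float,
    sigma: float = 0.01,
    n_frames: int = 400,
    t_max: float | None = None,
    seed: int = 0,
    channel: str = "qf",
) -> QSeries:
    """Exponentially decaying Q series with additive Gaussian noise.

    ``t_max`` defaults to two decay times (2 / rate), which keeps q well
    above the noise floor so the log-space fit is defined everywhere.
    """
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 2.0 / rate
    times = np.linspace(0.0, t_max, n_frames)
    q = np.exp(-rate * times) + sigma * rng.normal(size=n_frames)
    q = np.clip(q, 1e-12, None)
    return QSeries(
        times=times,
        qf=q if channel == "qf" else None,
        qb=q if channel == "qb" else None,
        n_native_tertiary=100,
        n_native_binding=100,
    )
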