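"""Descriptive ensemble observables.

Per-residue Cα fluctuations (RMSF), backbone φ/ψ circular variation,
helical content, bound-minus-apo distance-difference maps and
Rg/RMSD free-energy landscapes — the standard room-temperature ensemble
summaries used to compare apo and bound states of a chain.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage, stats

from .system_model import Ensemble, radius_of_gyration, superpose

__all__ = [
    "FreeEnergyLandscape",
    "ca_rmsf",
    "dihedral_variation",
    "helical_content",
    "distance_difference_map",
    "free_energy_landscape",
]

# φ/ψ window (degrees) counted as α-helical; a residue must additionally sit
# in a run of >= 3 consecutive helical residues.
HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-80.0, -5.0)
HELIX_MIN_RUN = 3


@dataclass
class FreeEnergyLandscape:
    """Probability and free-energy surface over (Rg, RMSD)."""

    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    probability: np.ndarray  # (n_rg, n_rmsd), sums to 1
    free_energy: np.ndarray  # -ln(P / P_max), kT; +inf on empty cells
    basins: list[dict]  # cells with F < 1 kT, connected components

    @property
    def occupied(self) -> np.ndarray:
        return self.probability > 0


def _superpose_to_mean(frames: np.ndarray, n_rounds: int = 2) -> np.ndarray:
    """Superpose all frames onto their iteratively refined mean structure.

    Frames are first aligned on the first frame so the procedure (and hence
    the RMSF) is invariant to rigid motions applied to the input ensemble.
    """
    fitted = frames.copy()
    sel = np.arange(frames.shape[1])
    for f in range(1, fitted.shape[0]):
        fit = superpose(fitted[f], fitted[0], sel)
        fitted[f] = fit.apply(fitted[f])
    fitted -= fitted[0].mean(axis=0)
    for _ in range(n_rounds):
        mean = fitted.mean(axis=0)
        for f in range(fitted.shape[0]):
            fit = superpose(fitted[f], mean, sel)
            fitted[f] = fit.apply(fitted[f])
    return fitted


def ca_rmsf(ensemble: Ensemble) -> np.ndarray:
    """Per-residue Cα root-mean-square fluctuation, Å.

    Frames are superposed on the ensemble-mean Cα structure (two rounds of
    mean refinement) before the fluctuation is measured.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca = ensemble.system.ca_indices()
    fitted = _superpose_to_mean(ensemble.frames[:, ca, :])
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """φ and ψ per frame and residue, degrees; NaN where undefined.

    φ_i needs C(i-1) and ψ_i needs N(i+1); chain termini are NaN.
    """
    system = ensemble.system
    n_res = system.n_residues
    atom = {}
    for name in ("N", "CA", "C"):
        idx = np.full(n_res, -1, dtype=int)
        for a in np.flatnonzero(system.atom_name == name):
            idx[system.atom_res[a]] = a
        atom[name] = idx
    phi = np.full((ensemble.n_frames, n_res), np.nan)
    psi = np.full((ensemble.n_frames, n_res), np.nan)
    same_chain = lambda i, j: system.res_chain[i] == system.res_chain[j]
    for f in range(ensemble.n_frames):
        xyz = ensemble.frames[f]
        for r in range(n_res):
            if (
                r > 0
                and same_chain(r - 1, r)
                and atom["C"][r - 1] >= 0
                and min(atom["N"][r], atom["CA"][r], atom["C"][r]) >= 0
            ):
                phi[f, r] = _dihedral(
                    xyz[atom["C"][r - 1]], xyz[atom["N"][r]],
                    xyz[atom["CA"][r]], xyz[atom["C"][r]],
                )
            if (
                r + 1 < n_res
                and same_chain(r, r + 1)
                and atom["N"][r + 1] >= 0
                and min(atom["N"][r], atom["CA"][r], atom["C"][r]) >= 0
            ):
                psi[f, r] = _dihedral(
                    xyz[atom["N"][r]], xyz[atom["CA"][r]],
                    xyz[atom["C"][r]], xyz[atom["N"][r + 1]],
                )
    return phi, psi


def _circular_sd_deg(angles: np.ndarray) -> float:
    return float(np.degrees(stats.circstd(np.radians(angles))))


def dihedral_variation(ensemble: Ensemble) -> np.ndarray:
    """Per-residue mean circular SD of φ and ψ across frames, degrees.

    Undefined (NaN) for residues lacking either dihedral (chain termini).
    Circular statistics make the result invariant under the ±180° wrap.
    """
    phi, psi = backbone_dihedrals(ensemble)
    n_res = phi.shape[1]
    out = np.full(n_res, np.nan)
    for r in range(n_res):
        if np.any(np.isnan(phi[:, r])) or np.any(np.isnan(psi[:, r])):
            continue
        out[r] = 0.5 * (_circular_sd_deg(phi[:, r]) + _circular_sd_deg(psi[:, r]))
    return out


def helical_content(ensemble: Ensemble, region: tuple[int, int] | None = None) -> float:
    """Fraction of residue-frames that are α-helical.

    A residue-frame is helical iff φ ∈ [-100°, -30°], ψ ∈ [-80°, -5°] and
    the residue sits in a run of at least 3 consecutive helical residues in
    that frame.  ``region`` restricts the count to internal residue ids
    [lo, hi] (inclusive); runs are still detected over the whole chain.
    Residue-frames without both dihedrals are excluded from the denominator.
    """
    phi, psi = backbone_dihedrals(ensemble)
    in_window = (
        (phi >= HELIX_PHI_RANGE[0]) & (phi <= HELIX_PHI_RANGE[1])
        & (psi >= HELIX_PSI_RANGE[0]) & (psi <= HELIX_PSI_RANGE[1])
    )
    system = ensemble.system
    helical = np.zeros_like(in_window, dtype=bool)
    for f in range(in_window.shape[0]):
        run_start = None
        flags = in_window[f]
        for r in range(system.n_residues + 1):
            ok = (
                r < system.n_residues
                and flags[r]
                and (r == 0 or system.res_chain[r] == system.res_chain[r - 1])
            )
            # a chain break ends the current run
            if r < system.n_residues and r > 0 and system.res_chain[r] != system.res_chain[r - 1]:
                if run_start is not None and r - run_start >= HELIX_MIN_RUN:
                    helical[f, run_start:r] = True
                run_start = r if (r < system.n_residues and flags[r]) else None
                continue
            if ok:
                if run_start is None:
                    run_start = r
            else:
                if run_start is not None and r - run_start >= HELIX_MIN_RUN:
                    helical[f, run_start:r] = True
                run_start = None
    defined = ~np.isnan(phi) & ~np.isnan(psi)
    if region is not None:
        lo, hi = region
        mask = np.zeros(system.n_residues, dtype=bool)
        mask[lo : hi + 1] = True
        defined = defined & mask[None, :]
    total = defined.sum()
    if total == 0:
        raise ValueError("no residue-frames with defined dihedrals in the region")
    return float(np.sum(helical & defined) / total)


def distance_difference_map(bound: Ensemble, apo: Ensemble) -> np.ndarray:
    """D(i,j) = <|Cα_i - Cα_j|>_bound - <|Cα_i - Cα_j|>_apo, Å.

    Positive entries mean the residue pair is stretched apart in the bound
    state, negative entries that it is compacted.  Both ensembles must
    cover the same chain (equal residue counts).
    """
    ca_b = bound.system.ca_indices()
    ca_a = apo.system.ca_indices()
    if ca_b.size != ca_a.size:
        raise ValueError("bound and apo must have the same residues")

    def mean_distances(frames: np.ndarray) -> np.ndarray:
        diff = frames[:, :, None, :] - frames[:, None, :, :]
        return np.sqrt(np.sum(diff**2, axis=3)).mean(axis=0)

    return mean_distances(bound.frames[:, ca_b]) - mean_distances(apo.frames[:, ca_a])


def free_energy_landscape(
    ensemble: Ensemble,
    reference_coords: np.ndarray | None = None,
    rg_bin_width: float = 0.5,
    rmsd_bin_width: float = 0.5,
) -> FreeEnergyLandscape:
    """2D free-energy surface over (Rg, fitted Cα RMSD to the reference).

    F = -ln(P / P_max) in kT units; empty cells carry F = +inf.  Basins are
    connected components of cells with F < 1 kT, reported with their cell
    ranges and member frame ids.
    """
    if ensemble.n_frames < 50:
        warnings.warn(
            f"landscape from only {ensemble.n_frames} frames; statistics "
            "will be rough below ~50 frames",
            stacklevel=2,
        )
    system = ensemble.system
    if reference_coords is None:
        reference_coords = system.reference_coords
    ca = system.ca_indices()
    rg = np.array(
        [
            radius_of_gyration(ensemble.frames[f], masses=system.masses)
            for f in range(ensemble.n_frames)
        ]
    )
    dev = np.array(
        [
            superpose(ensemble.frames[f], reference_coords, ca).rmsd
            for f in range(ensemble.n_frames)
        ]
    )

    def edges(values: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + 0.5 * width, width)

    rg_edges = edges(rg, rg_bin_width)
    rmsd_edges = edges(dev, rmsd_bin_width)
    counts, _, _ = np.histogram2d(rg, dev, bins=(rg_edges, rmsd_edges))
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        free = np.where(prob > 0, -np.log(prob / prob.max()), np.inf)

    basin_mask = free < 1.0
    labels, n_basins = ndimage.label(basin_mask)
    rg_bin = np.clip(np.digitize(rg, rg_edges) - 1, 0, len(rg_edges) - 2)
    rmsd_bin = np.clip(np.digitize(dev, rmsd_edges) - 1, 0, len(rmsd_edges) - 2)
    basins = []
    for lab in range(1, n_basins + 1):
        cells = np.argwhere(labels == lab)
        member = np.flatnonzero(labels[rg_bin, rmsd_bin] == lab)
        basins.append(
            {
                "cells": cells,
                "rg_range": (
                    float(rg_edges[cells[:, 0].min()]),
                    float(rg_edges[cells[:, 0].max() + 1]),
                ),
                "rmsd_range": (
                    float(rmsd_edges[cells[:, 1].min()]),
                    float(rmsd_edges[cells[:, 1].max() + 1]),
                ),
                "frames": member,
                "mean_structure": ensemble.frames[member].mean(axis=0)
                if member.size
                else None,
            }
        )
    return FreeEnergyLandscape(
        rg_edges=rg_edges,
        rmsd_edges=rmsd_edges,
        probability=prob,
        free_energy=free,
        basins=basins,
    )
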