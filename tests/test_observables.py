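"""Ensemble observables: RMSF, dihedral statistics, helicity, maps, landscapes."""

import warnings

import numpy as np
import pytest

from helpers import make_system, random_rotation
from idpmech.ensemble_observables import (
    backbone_dihedrals,
    ca_rmsf,
    dihedral_variation,
    distance_difference_map,
    free_energy_landscape,
    helical_content,
)
from idpmech.system_model import Ensemble
from idpmech.synthetic_data import build_peptide


def _ca_chain(n=6, spacing=3.8):
    # zig-zag (non-collinear) so no single-atom displacement is congruent
    # to a rigid motion of the whole chain
    residues = []
    for i in range(n):
        xyz = (spacing * i, 1.5 * (i % 2), 0.8 * (i % 3))
        residues.append(("A", i + 1, "ALA", [("CA", "C", 13.0, xyz)]))
    return make_system(residues)


def _peptide_ensemble(phi_frames, psi_frames, seq=None):
    """Ensemble whose frame f realises torsions (phi_frames[f], psi_frames[f])."""
    n = len(phi_frames[0])
    seq = seq or ["ALA"] * n
    system = build_peptide(seq, phi_frames[0], psi_frames[0])
    frames = [
        build_peptide(seq, p, s).reference_coords for p, s in zip(phi_frames, psi_frames)
    ]
    return Ensemble(system=system, frames=np.asarray(frames),
                    times=np.arange(len(frames), dtype=float))


class TestCaRmsf:
    def test_identical_frames_zero(self, toy_system):
        frames = np.repeat(toy_system.reference_coords[None], 4, axis=0)
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(4.0))
        assert np.allclose(ca_rmsf(ens), 0.0)

    def test_single_oscillating_residue(self):
        # a long chain so the fit to the mean absorbs almost none of the
        # single-residue oscillation
        system = _ca_chain(60)
        ref = system.reference_coords
        up, down = ref.copy(), ref.copy()
        up[30, 1] += 1.0
        down[30, 1] -= 1.0
        ens = Ensemble(system=system, frames=np.array([up, down] * 2),
                       times=np.arange(4.0))
        rmsf = ca_rmsf(ens)
        assert rmsf[30] == pytest.approx(1.0, abs=0.05)
        assert np.all(rmsf[[0, 1, 59]] < 0.2)

    def test_matches_direct_two_pass_oracle(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack([ref + rng.normal(scale=0.3, size=ref.shape) for _ in range(6)])
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(6.0))
        rmsf = ca_rmsf(ens)
        # oracle: after the same mean-structure alignment, direct two-pass sum
        from idpmech.ensemble_observables import _superpose_to_mean

        ca = toy_system.ca_indices()
        fitted = _superpose_to_mean(frames[:, ca, :])
        mean = fitted.mean(axis=0)
        direct = np.array(
            [
                np.sqrt(sum(np.sum((fitted[f, i] - mean[i]) ** 2) for f in range(6)) / 6)
                for i in range(ca.size)
            ]
        )
        assert np.allclose(rmsf, direct, atol=1e-10)

    def test_rigid_motion_invariance(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack([ref + rng.normal(scale=0.3, size=ref.shape) for _ in range(5)])
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(5.0))
        base = ca_rmsf(ens)
        moved = np.stack([f @ random_rotation(rng).T + rng.normal(size=3) * 5 for f in frames])
        ens2 = Ensemble(system=toy_system, frames=moved, times=np.arange(5.0))
        assert np.allclose(ca_rmsf(ens2), base, atol=1e-8)


class TestDihedrals:
    def test_planted_torsions_recovered(self, rng):
        phi = rng.uniform(-150, -50, size=8)
        psi = rng.uniform(-60, 150, size=8)
        ens = _peptide_ensemble([phi], [psi])
        got_phi, got_psi = backbone_dihedrals(ens)
        assert np.allclose(got_phi[0][1:], phi[1:], atol=1e-6)
        assert np.allclose(got_psi[0][:-1], psi[:-1], atol=1e-6)

    def test_constant_dihedrals_zero_variation(self):
        phi = np.full(6, -70.0)
        psi = np.full(6, -40.0)
        ens = _peptide_ensemble([phi] * 3, [psi] * 3)
        var = dihedral_variation(ens)
        internal = ~np.isnan(var)
        assert np.any(internal)
        assert np.allclose(var[internal], 0.0, atol=1e-6)

    def test_alternating_ten_degrees(self):
        base_phi = np.full(6, -70.0)
        psi = np.full(6, -40.0)
        frames_phi = [base_phi + 10.0, base_phi - 10.0] * 4
        ens = _peptide_ensemble(frames_phi, [psi] * 8)
        var = dihedral_variation(ens)
        # psi constant, phi circular SD = 10 -> mean of (10, 0) = 5
        internal = ~np.isnan(var)
        assert np.allclose(var[internal], 5.0, atol=0.1)

    def test_wraparound_invariance(self):
        """Angles straddling ±180° give the same spread as shifted data."""
        psi_a = [np.full(6, 175.0), np.full(6, -175.0)] * 2
        psi_b = [np.full(6, -5.0), np.full(6, 5.0)] * 2
        phi = np.full(6, -70.0)
        var_a = dihedral_variation(_peptide_ensemble([phi] * 4, psi_a))
        var_b = dihedral_variation(_peptide_ensemble([phi] * 4, psi_b))
        mask = ~np.isnan(var_a)
        assert np.allclose(var_a[mask], var_b[mask], atol=0.1)


class TestHelicalContent:
    def test_ideal_helix_is_one(self):
        ens = _peptide_ensemble([np.full(10, -57.0)], [np.full(10, -47.0)])
        assert helical_content(ens) == 1.0

    def test_extended_strand_is_zero(self):
        ens = _peptide_ensemble([np.full(10, -120.0)], [np.full(10, 120.0)])
        assert helical_content(ens) == 0.0

    def test_half_helical_matches_hand_count(self):
        phi = np.concatenate([np.full(10, -57.0), np.full(10, -120.0)])
        psi = np.concatenate([np.full(10, -47.0), np.full(10, 120.0)])
        ens = _peptide_ensemble([phi], [psi])
        # hand count: phi defined for residues 1..19, psi for 0..18; both
        # defined on 1..18 (18 residue-frames); helical run = residues 0..9,
        # of which 1..9 have both dihedrals => 9/18
        assert helical_content(ens) == pytest.approx(9 / 18)

    def test_short_runs_not_counted(self):
        # two isolated helical residues inside a strand: run < 3
        phi = np.full(12, -120.0)
        psi = np.full(12, 120.0)
        phi[5:7] = -57.0
        psi[5:7] = -47.0
        ens = _peptide_ensemble([phi], [psi])
        assert helical_content(ens) == 0.0

    def test_region_restriction(self):
        phi = np.concatenate([np.full(10, -57.0), np.full(10, -120.0)])
        psi = np.concatenate([np.full(10, -47.0), np.full(10, 120.0)])
        ens = _peptide_ensemble([phi], [psi])
        assert helical_content(ens, region=(2, 7)) == 1.0
        assert helical_content(ens, region=(12, 17)) == 0.0


class TestDistanceDifferenceMap:
    def test_equal_ensembles_zero(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack([ref + rng.normal(scale=0.2, size=ref.shape) for _ in range(4)])
        a = Ensemble(system=toy_system, frames=frames, times=np.arange(4.0))
        assert np.allclose(distance_difference_map(a, a), 0.0, atol=1e-12)

    def test_uniform_scaling_positive_offdiagonal(self, toy_system):
        ref = toy_system.reference_coords
        apo = Ensemble(system=toy_system, frames=ref[None], times=np.zeros(1))
        bound = Ensemble(system=toy_system, frames=(ref * 1.1)[None], times=np.zeros(1))
        ddm = distance_difference_map(bound, apo)
        off = ~np.eye(ddm.shape[0], dtype=bool)
        assert np.all(ddm[off] > 0)
        assert np.allclose(np.diag(ddm), 0.0)

    def test_antisymmetric_under_role_swap(self, toy_system, rng):
        ref = toy_system.reference_coords
        a = Ensemble(system=toy_system,
                     frames=np.stack([ref + rng.normal(scale=0.3, size=ref.shape)
                                      for _ in range(3)]),
                     times=np.arange(3.0))
        b = Ensemble(system=toy_system,
                     frames=np.stack([ref + rng.normal(scale=0.6, size=ref.shape)
                                      for _ in range(3)]),
                     times=np.arange(3.0))
        assert np.allclose(
            distance_difference_map(a, b), -distance_difference_map(b, a), atol=1e-12
        )

    def test_matches_averaging_oracle(self, toy_system, rng):
        ref = toy_system.reference_coords
        fa = np.stack([ref + rng.normal(scale=0.4, size=ref.shape) for _ in range(3)])
        fb = np.stack([ref + rng.normal(scale=0.4, size=ref.shape) for _ in range(2)])
        a = Ensemble(system=toy_system, frames=fa, times=np.arange(3.0))
        b = Ensemble(system=toy_system, frames=fb, times=np.arange(2.0))
        ddm = distance_difference_map(a, b)
        ca = toy_system.ca_indices()
        i, j = 2, 7
        da = np.mean([np.linalg.norm(f[ca[i]] - f[ca[j]]) for f in fa])
        db = np.mean([np.linalg.norm(f[ca[i]] - f[ca[j]]) for f in fb])
        assert ddm[i, j] == pytest.approx(da - db, abs=1e-10)


class TestFreeEnergyLandscape:
    def _landscape(self, ens, **kw):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return free_energy_landscape(ens, **kw)

    def test_identical_frames_single_zero_cell(self, toy_system):
        frames = np.repeat(toy_system.reference_coords[None], 5, axis=0)
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(5.0))
        fel = self._landscape(ens)
        assert (fel.probability > 0).sum() == 1
        assert fel.free_energy.min() == 0.0

    def test_two_equal_conformers_two_zero_cells(self, toy_system):
        ref = toy_system.reference_coords
        frames = np.concatenate(
            [np.repeat(ref[None], 4, axis=0), np.repeat((ref * 1.3)[None], 4, axis=0)]
        )
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(8.0))
        fel = self._landscape(ens)
        zero_cells = np.argwhere(fel.free_energy == 0.0)
        assert len(zero_cells) == 2

    def test_probability_normalised_and_min_f_zero(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack(
            [ref * rng.uniform(0.9, 1.4) + rng.normal(scale=0.5, size=ref.shape)
             for _ in range(60)]
        )
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(60.0))
        fel = free_energy_landscape(ens)
        assert fel.probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert fel.free_energy.min() == 0.0
        assert np.all(np.isinf(fel.free_energy[fel.probability == 0]))

    def test_basins_contain_frames(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack(
            [ref + rng.normal(scale=0.3, size=ref.shape) for _ in range(60)]
        )
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(60.0))
        fel = free_energy_landscape(ens)
        assert fel.basins
        total = sum(b["frames"].size for b in fel.basins)
        assert 0 < total <= 60
        assert all(b["mean_structure"] is not None for b in fel.basins)
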