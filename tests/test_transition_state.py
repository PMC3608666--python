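"""Sammon mapping, trajectory segmentation, TS extraction and Phi-values."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from helpers import two_cb_residues
from idpmech.contacts import native_contacts
from idpmech.system_model import Ensemble, rmsd
from idpmech.synthetic_data import sample_clustered_trajectory
from idpmech.transition_state import (
    ClusterSegmentation,
    phi_values,
    rmsd_matrix,
    sammon_map,
    segment_by_time,
    ts_ensemble,
)


class TestRmsdMatrix:
    def test_identical_frames_zero(self, toy_system):
        frames = np.repeat(toy_system.reference_coords[None], 2, axis=0)
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(2.0))
        assert np.allclose(rmsd_matrix(ens).matrix, 0.0)

    def test_rigidly_moved_frame_near_zero(self, toy_system, rng):
        from helpers import random_rotation

        ref = toy_system.reference_coords
        moved = ref @ random_rotation(rng).T + np.array([4.0, 5.0, 6.0])
        frames = np.stack([ref, ref + rng.normal(size=ref.shape), moved])
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(3.0))
        mat = rmsd_matrix(ens).matrix
        assert mat[0, 2] < 1e-8

    def test_matches_per_pair_oracle(self, toy_system, rng):
        ref = toy_system.reference_coords
        frames = np.stack([ref + rng.normal(scale=0.5, size=ref.shape) for _ in range(6)])
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(6.0))
        mat = rmsd_matrix(ens, stride=2)
        ca = toy_system.ca_indices()
        for a, i in enumerate(mat.frame_indices):
            for b, j in enumerate(mat.frame_indices):
                expected = rmsd(frames[i], frames[j], atom_selection=ca, fit=True)
                assert mat.matrix[a, b] == pytest.approx(expected, abs=1e-8)

    def test_stride_too_coarse_rejected(self, toy_system):
        frames = np.repeat(toy_system.reference_coords[None], 3, axis=0)
        ens = Ensemble(system=toy_system, frames=frames, times=np.arange(3.0))
        with pytest.raises(ValueError, match="fewer than 2"):
            rmsd_matrix(ens, stride=5)


class TestSammonMap:
    def test_planar_configuration_embeds_exactly(self, rng):
        pts = rng.normal(size=(15, 2)) * 4.0
        proj = sammon_map(squareform(pdist(pts)), seed=0)
        assert proj.stress < 1e-3

    def test_equilateral_triangle(self):
        d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        proj = sammon_map(d, seed=0)
        assert proj.stress < 1e-6
        dd = pdist(proj.points)
        assert np.all(np.abs(dd - 1.0) < 1e-3)

    def test_stress_monotone_nonincreasing(self, rng):
        d = squareform(pdist(rng.normal(size=(10, 5))))
        proj = sammon_map(d, seed=0)
        assert np.all(np.diff(proj.stress_history) <= 1e-15)

    def test_never_worse_than_classical_scaling_start(self, rng):
        d = squareform(pdist(rng.normal(size=(10, 6))))
        proj = sammon_map(d, seed=0)
        assert proj.stress <= proj.stress_history[0] + 1e-15

    def test_deterministic_under_seed(self, rng):
        d = squareform(pdist(rng.normal(size=(12, 4))))
        a = sammon_map(d, seed=7)
        b = sammon_map(d, seed=7)
        assert np.array_equal(a.points, b.points)
        assert a.stress == b.stress

    def test_zero_distance_jitter_warns(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 1.0
        # frames 1 and 2 identical: d(1,2)=0, d(0,2)=1
        d[0, 2] = d[2, 0] = 1.0
        with pytest.warns(UserWarning, match="jitter"):
            proj = sammon_map(d, seed=0)
        assert np.all(np.isfinite(proj.points))


class TestSegmentation:
    def test_planted_three_basins_recovered(self, toy_system, small_spec):
        for seed in (0, 1, 2):
            ens, planted = sample_clustered_trajectory(toy_system, small_spec, seed=seed)
            mat = rmsd_matrix(ens)
            seg = segment_by_time(sammon_map(mat, seed=0), mat.times)
            assert seg.n_segments == planted.n_segments
            for found, true in zip(seg.segments, planted.segments):
                assert abs(found[0] - true[0]) <= 2

    def test_single_blob_single_segment(self, rng):
        pts = rng.normal(size=(60, 2))
        from idpmech.transition_state import Projection2D

        proj = Projection2D(points=pts, stress=0.0, n_iter=0, seed=0)
        seg = segment_by_time(proj, np.arange(60.0))
        assert seg.n_segments == 1

    def test_infinite_jump_factor_single_segment(self, toy_system, small_spec):
        ens, _ = sample_clustered_trajectory(toy_system, small_spec, seed=5)
        mat = rmsd_matrix(ens)
        proj = sammon_map(mat, seed=0)
        seg = segment_by_time(proj, mat.times, jump_factor=1e12)
        assert seg.n_segments == 1

    def test_barrier_times_between_segments(self, toy_system, small_spec):
        ens, planted = sample_clustered_trajectory(toy_system, small_spec, seed=1)
        mat = rmsd_matrix(ens)
        seg = segment_by_time(sammon_map(mat, seed=0), mat.times)
        assert len(seg.barrier_times) == seg.n_segments - 1
        for i, barrier in enumerate(seg.barrier_times):
            t_before = mat.times[seg.segments[i][1]]
            t_after = mat.times[seg.segments[i + 1][0]]
            assert t_before < barrier < t_after


class TestTsEnsemble:
    def _grid_ensemble(self, toy_system, n=101, dt=20.0):
        frames = np.repeat(toy_system.reference_coords[None], n, axis=0)
        return Ensemble(system=toy_system, frames=frames, times=np.arange(n) * dt)

    def test_window_arithmetic_on_grid(self, toy_system):
        ens = self._grid_ensemble(toy_system)
        seg = ClusterSegmentation(
            segments=[(0, 47, 0), (48, 100, 1)], barrier_times=[960.0]
        )
        ts = ts_ensemble(ens, seg, barrier_index=0, half_window_ps=40.0)
        assert ts.n_frames == 5
        assert np.allclose(ts.times, [920.0, 940.0, 960.0, 980.0, 1000.0])

    def test_window_smaller_than_sampling_errors(self, toy_system):
        ens = self._grid_ensemble(toy_system)
        seg = ClusterSegmentation(
            segments=[(0, 47, 0), (48, 100, 1)], barrier_times=[970.0]
        )
        with pytest.raises(ValueError, match="widen"):
            ts_ensemble(ens, seg, barrier_index=0, half_window_ps=5.0)

    def test_no_barrier_errors(self, toy_system):
        ens = self._grid_ensemble(toy_system)
        seg = ClusterSegmentation(segments=[(0, 100, 0)], barrier_times=[])
        with pytest.raises(ValueError, match="no barriers"):
            ts_ensemble(ens, seg)

    def test_ts_window_excludes_terminal_cores(self, toy_system, small_spec):
        ens, planted = sample_clustered_trajectory(toy_system, small_spec, seed=2)
        ts = ts_ensemble(ens, planted, barrier_index=0,
                         half_window_ps=2 * small_spec.cluster_frame_interval_ps)
        first_core = ens.times[planted.segments[0][0]]
        last_core = ens.times[planted.segments[-1][1]]
        assert first_core not in ts.times
        assert last_core not in ts.times


class TestPhiValues:
    def _contact_toggle_ensembles(self):
        """4-residue chain pair with one native contact that toggles."""
        closed = two_cb_residues(5.0)
        open_coords = closed.reference_coords.copy()
        open_coords[2:, 0] += 10.0  # separate the second residue
        native = native_contacts(closed.reference_coords, closed)
        assert len(native) == 1

        def ens(frames):
            return Ensemble(system=closed, frames=np.asarray(frames),
                            times=np.arange(len(frames), dtype=float))

        folded = ens([closed.reference_coords] * 4)
        unfolded = ens([open_coords] * 4)
        half = ens([closed.reference_coords, open_coords,
                    closed.reference_coords, open_coords])
        return closed, native, folded, unfolded, half

    def test_ts_equals_folded_gives_one(self, toy_system, toy_native, rng):
        ref = toy_system.reference_coords
        folded = Ensemble(
            system=toy_system,
            frames=np.stack([ref + rng.normal(scale=0.1, size=ref.shape) for _ in range(4)]),
            times=np.arange(4.0),
        )
        unfolded = Ensemble(
            system=toy_system,
            frames=np.stack([ref * 8.0 + rng.normal(size=ref.shape) for _ in range(4)]),
            times=np.arange(4.0),
        )
        profile = phi_values(folded, folded, unfolded, toy_native)
        assert np.any(profile.defined)
        assert np.all(profile.phi_clamped[profile.defined] == 1.0)

    def test_ts_equals_unfolded_gives_zero(self, toy_system, toy_native, rng):
        ref = toy_system.reference_coords
        folded = Ensemble(
            system=toy_system,
            frames=np.stack([ref, ref]),
            times=np.arange(2.0),
        )
        unfolded = Ensemble(
            system=toy_system,
            frames=np.stack([ref * 8.0, ref * 8.0 + 1.0]),
            times=np.arange(2.0),
        )
        profile = phi_values(unfolded, folded, unfolded, toy_native)
        assert np.all(profile.phi_clamped[profile.defined] == 0.0)

    def test_half_formed_contact_gives_half(self):
        system, native, folded, unfolded, half = self._contact_toggle_ensembles()
        profile = phi_values(half, folded, unfolded, native)
        assert profile.n_folded[0] == 1.0
        assert profile.n_unfolded[0] == 0.0
        assert profile.n_ts[0] == 0.5
        assert profile.phi_raw[0] == pytest.approx(0.5)

    def test_no_native_contacts_undefined(self):
        system, native, folded, unfolded, half = self._contact_toggle_ensembles()
        # an extra residue with no native contacts stays NaN: simulate by
        # checking a residue index outside the contact
        profile = phi_values(half, folded, unfolded, native)
        assert profile.defined.sum() == 2  # only the two contact partners

    def test_invariant_under_frame_reordering(self):
        system, native, folded, unfolded, half = self._contact_toggle_ensembles()
        reordered = Ensemble(
            system=system,
            frames=half.frames[[3, 1, 2, 0]],
            times=half.times,
        )
        a = phi_values(half, folded, unfolded, native)
        b = phi_values(reordered, folded, unfolded, native)
        assert np.array_equal(a.phi_raw, b.phi_raw, equal_nan=True)

    def test_monotone_in_folded_mixture(self):
        """phi grows monotonically with the folded fraction of the TS."""
        system, native, folded, unfolded, _ = self._contact_toggle_ensembles()
        closed = system.reference_coords
        opened = unfolded.frames[0]
        phis = []
        for n_closed in (1, 2, 3):
            frames = [closed] * n_closed + [opened] * (4 - n_closed)
            ts = Ensemble(system=system, frames=np.asarray(frames),
                          times=np.arange(4.0))
            phis.append(phi_values(ts, folded, unfolded, native).phi_raw[0])
        assert phis[0] < phis[1] < phis[2]
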