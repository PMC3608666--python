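"""Conformational-selection vs induced-fit statistics."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import random_rotation
from idpmech.csif import (
    DistanceBins,
    csif_analysis,
    delta_statistic,
    distance_bins,
    ks_map,
    local_rmsd_profile,
    mechanism_verdict,
    pair_bound_apo,
    pair_deviations,
)
from idpmech.system_model import Ensemble, superpose
from idpmech.synthetic_data import sample_csif_ensembles


@pytest.fixture(scope="module")
def mixed_ensembles(toy_system, small_spec):
    return sample_csif_ensembles(toy_system, small_spec, mechanism="mixed")


class TestPairing:
    def test_exact_copy_is_most_similar_with_zero_rmsd(self, toy_system, small_spec):
        bound, apo, _ = sample_csif_ensembles(toy_system, small_spec, "cs_dominant")
        bound_chain = bound.extract_chain("A")
        # splice an exact copy of a sampled bound frame into the apo ensemble
        frames = apo.frames.copy()
        frames[3] = bound_chain.frames[0]
        apo2 = Ensemble(system=apo.system, frames=frames, times=apo.times)
        pairs = pair_bound_apo(bound_chain, apo2, n_bound=5, n_apo=10)
        assert pairs.apo_frames[pairs.most_similar[0]] == 3
        assert pairs.rmsd_best[0] < 1e-9

    def test_default_grid_has_hundred_pairs(self, mixed_ensembles):
        bound, apo, _ = mixed_ensembles
        pairs = pair_bound_apo(bound.extract_chain("A"), apo)
        assert pairs.grid.shape == (10, 10)
        assert pairs.n_pairs == 100

    def test_argmin_matches_exhaustive_oracle(self, mixed_ensembles):
        bound, apo, _ = mixed_ensembles
        bound_chain = bound.extract_chain("A")
        pairs = pair_bound_apo(bound_chain, apo, n_bound=6, n_apo=8)
        ca = bound_chain.system.ca_indices()
        for i, bf in enumerate(pairs.bound_frames):
            grid = [
                superpose(apo.frames[af], bound_chain.frames[bf], ca).rmsd
                for af in pairs.apo_frames
            ]
            assert pairs.most_similar[i] == int(np.argmin(grid))
            assert pairs.grid[i] == pytest.approx(grid, abs=1e-9)


class TestDistanceBins:
    def test_floor_arithmetic(self):
        coords = np.array([[0.74, 0.0, 0.0], [1.2, 0.0, 0.0]])
        partner = np.zeros((2, 3))
        bins = distance_bins(coords, partner, np.ones(2))
        assert bins.bin_index[0] == 1  # [0.5, 1.0)
        assert bins.bin_index[1] == 2  # [1.0, 1.5)

    def test_exactly_fifty_is_overflow(self):
        coords = np.array([[50.0, 0.0, 0.0], [49.99, 0.0, 0.0]])
        bins = distance_bins(coords, np.zeros((1, 3)), np.ones(1))
        assert bins.bin_index[0] == -1
        assert bins.bin_index[1] == 99

    def test_partition_property(self, rng):
        coords = rng.uniform(-60, 60, size=(500, 3))
        bins = distance_bins(coords, np.zeros((1, 3)), np.ones(1))
        inside = bins.distances < 50.0
        assert np.all(bins.bin_index[inside] >= 0)
        assert np.all(bins.bin_index[~inside] == -1)
        # every inside atom in exactly one bin
        counts = np.zeros(bins.n_bins, dtype=int)
        for b in range(bins.n_bins):
            counts[b] = bins.members(b).size
        assert counts.sum() == inside.sum()
        for a in np.flatnonzero(inside):
            b = bins.bin_index[a]
            assert bins.edges[b] <= bins.distances[a] < bins.edges[b + 1]

    def test_mass_weighted_centroid(self):
        partner = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        bins = distance_bins(np.zeros((1, 3)), partner, np.array([3.0, 1.0]))
        assert bins.centroid == pytest.approx([2.5, 0.0, 0.0])


class TestLocalRmsdProfile:
    def test_identical_pair_is_zero(self, mixed_ensembles):
        bound, apo, _ = mixed_ensembles
        chain = bound.extract_chain("A")
        ca = chain.system.ca_indices()
        dev = pair_deviations(chain.frames[0], chain.frames[0], ca)
        bins = distance_bins(chain.frames[0], bound.frames[0], np.ones(bound.frames[0].shape[0]))
        profile = local_rmsd_profile(dev, bins)
        defined = ~np.isnan(profile)
        assert np.any(defined)
        assert np.all(profile[defined] < 1e-10)

    def test_far_only_perturbation_localises(self, rng):
        coords = np.zeros((200, 3))
        coords[:, 0] = np.linspace(0.5, 49.5, 200)
        partner = np.zeros((1, 3))
        bins = distance_bins(coords, partner, np.ones(1))
        dev = np.zeros(200)
        far = bins.distances > 25.0
        dev[far] = rng.uniform(1.0, 2.0, size=far.sum())
        profile = local_rmsd_profile(dev, bins)
        edges_mid = 0.5 * (bins.edges[:-1] + bins.edges[1:])
        defined = ~np.isnan(profile)
        assert np.all(profile[defined & (edges_mid < 25.0)] == 0.0)
        assert np.all(profile[defined & (edges_mid > 26.0)] > 0.0)

    def test_uniform_displacement_flat_profile(self, rng):
        coords = rng.uniform(-30, 30, size=(3000, 3))
        bins = distance_bins(coords, np.zeros((1, 3)), np.ones(1))
        dev = np.abs(rng.normal(0.0, 1.0, size=3000))
        profile = local_rmsd_profile(dev, bins)
        populated = np.array(
            [bins.members(b).size >= 30 for b in range(bins.n_bins)]
        )
        vals = profile[populated]
        # per-bin RMSD of iid deviations is flat across bins
        assert vals.std() / vals.mean() < 0.25


class TestKsMap:
    def _one_bin(self, n):
        return DistanceBins(
            centroid=np.zeros(3),
            distances=np.full(n, 0.2),
            bin_index=np.zeros(n, dtype=int),
            edges=np.arange(101) * 0.5,
        )

    def test_identical_samples_p_one(self, rng):
        dev = rng.uniform(size=50)
        km = ks_map([dev], [self._one_bin(50)], [dev])
        assert km.p_values[0, 0] == pytest.approx(1.0)

    def test_shifted_samples_highly_significant(self, rng):
        dev = rng.normal(0.0, 1.0, size=200) + 5.0
        base = rng.normal(0.0, 1.0, size=200)
        km = ks_map([dev], [self._one_bin(200)], [base])
        assert km.p_values[0, 0] < 1e-6

    def test_small_bins_undefined(self, rng):
        bins = DistanceBins(
            centroid=np.zeros(3),
            distances=np.array([0.2]),
            bin_index=np.array([0]),
            edges=np.arange(101) * 0.5,
        )
        km = ks_map([np.array([1.0])], [bins], [np.array([1.1])])
        assert np.isnan(km.p_values[0, 0])


class TestDeltaStatistic:
    def test_identical_distributions_zero(self, rng):
        vals = rng.uniform(1.0, 3.0, size=50)
        assert delta_statistic(vals, vals).delta == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_difference(self):
        stat = delta_statistic(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert stat.delta == pytest.approx(1.0)
        assert stat.n_cs == 3 and stat.n_if == 3

    def test_antisymmetric_under_swap(self, rng):
        cs = rng.gamma(2.0, 1.0, size=40)
        iv = rng.gamma(3.0, 0.5, size=60)
        assert delta_statistic(cs, iv).delta == pytest.approx(
            -delta_statistic(iv, cs).delta, abs=1e-12
        )

    def test_bin_width_independent(self, rng):
        cs = rng.gamma(2.0, 1.0, size=40)
        iv = rng.gamma(3.0, 0.5, size=60)
        deltas = [delta_statistic(cs, iv, bin_width=w).delta for w in (0.1, 0.25, 1.0)]
        assert np.ptp(deltas) < 1e-12

    def test_histogram_frequencies_sum_to_n(self, rng):
        vals = rng.uniform(0.0, 5.0, size=123)
        stat = delta_statistic(vals, vals)
        assert sum(f for _, f in stat.cs_histogram) == 123

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            delta_statistic(np.array([]), np.array([1.0]))

    @given(
        cs=st.lists(st.floats(0.01, 20.0), min_size=1, max_size=40),
        iv=st.lists(st.floats(0.01, 20.0), min_size=1, max_size=40),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_delta_equals_mean_difference_property(self, cs, iv):
        """Δ reduces to the difference of sample means for any inputs."""
        stat = delta_statistic(np.array(cs), np.array(iv))
        assert stat.delta == pytest.approx(np.mean(cs) - np.mean(iv), abs=1e-9)


class TestVerdict:
    @pytest.mark.parametrize(
        "dg,dl,expected",
        [
            (1.0, -1.0, "global conformational selection with local induced fit"),
            (1.0, 1.0, "global conformational selection with local conformational selection"),
            (-1.0, -1.0, "global induced fit with local induced fit"),
            (0.0, 0.0, "indeterminate"),
        ],
    )
    def test_labels(self, dg, dl, expected):
        assert mechanism_verdict(dg, dl) == expected


class TestCsifPipeline:
    def test_planted_mixed_mechanism_recovered(self, mixed_ensembles):
        bound, apo, truth = mixed_ensembles
        result = csif_analysis(bound, apo, "A", "B", compute_ks=False)
        assert result.delta_global.delta > 0
        assert result.delta_local.delta < 0
        assert "global conformational selection" in result.verdict
        assert "local induced fit" in result.verdict

    def test_ks_map_flags_interface_in_if_mechanism(self, toy_system, small_spec):
        bound, apo, _ = sample_csif_ensembles(toy_system, small_spec, "if_dominant")
        result = csif_analysis(bound, apo, "A", "B", compute_ks=True)
        # in deformed bins the bound-vs-apo deviations differ from the
        # apo-vs-apo baseline: most pairs should be significant somewhere
        assert np.nanmax(result.ks.fraction_lt) > 0.5

    def test_invariant_to_rigid_motion_of_apo(self, mixed_ensembles, rng):
        bound, apo, _ = mixed_ensembles
        base = csif_analysis(bound, apo, "A", "B", compute_ks=False)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 20.0
        moved = Ensemble(
            system=apo.system,
            frames=apo.frames @ rot.T + shift,
            times=apo.times,
        )
        res = csif_analysis(bound, moved, "A", "B", compute_ks=False)
        assert res.delta_global.delta == pytest.approx(base.delta_global.delta, abs=1e-8)
        assert res.delta_local.delta == pytest.approx(base.delta_local.delta, abs=1e-8)
        assert np.allclose(res.pairs.grid, base.pairs.grid, atol=1e-8)

    def test_atom_mismatch_rejected(self, mixed_ensembles):
        bound, apo, _ = mixed_ensembles
        with pytest.raises(ValueError, match="do not match"):
            csif_analysis(bound, apo, "B", "A", compute_ks=False)
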