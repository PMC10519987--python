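"""Stable pairs, ring geometry, master trajectories, RMSD and clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ctdkit as ck
from ctdkit.contacts import ContactKey, ContactTable
from ctdkit.model import Frame, Topology, Trajectory, ValidationError
from ctdkit.pairgeom import (
    MasterTrajectory,
    build_master_trajectory,
    distance_distribution,
    gromos_cluster,
    occupancy_curve,
    pair_rmsd,
    residue_cog,
    ring_cog_distance,
    rmsd_matrix,
    stable_pairs,
)

from conftest import brute_force_gromos, make_pair_config


def _table_with(freqs, n_frames=100):
    counts = {}
    for k, (key, f) in enumerate(freqs.items()):
        counts[key] = int(round(f * n_frames))
    return ContactTable(scope="inter", window_start_ps=0, window_end_ps=0,
                        stride_ps=1000, n_frames_analyzed=n_frames, counts=counts)


class TestStablePairs:
    def test_threshold_is_strict(self):
        keys = [ContactKey("A", i, "B", i) for i in (1, 2, 3)]
        table = _table_with(dict(zip(keys, [0.11, 0.10, 0.09])))
        assert stable_pairs(table, 0.10) == [keys[0]]

    def test_sorted_by_descending_frequency(self):
        keys = [ContactKey("A", i, "B", i) for i in (1, 2, 3)]
        table = _table_with(dict(zip(keys, [0.2, 0.9, 0.5])))
        assert stable_pairs(table, 0.1) == [keys[1], keys[2], keys[0]]

    def test_empty_and_zero_threshold(self):
        assert stable_pairs(_table_with({}), 0.1) == []
        keys = [ContactKey("A", 1, "B", 1)]
        table = _table_with({keys[0]: 0.01})
        assert stable_pairs(table, 0.0) == keys


def _pro_tyr_frame(offset=(4.0, 0.0, 0.0), box=None):
    """Pro and Tyr residues on separate chains, Tyr shifted by `offset`."""
    ch_p, xyz_p = ck.build_chain("P", seed=1, chain_id="A")
    ch_y, xyz_y = ck.build_chain("Y", seed=2, chain_id="B")
    top = Topology([ch_p, ch_y])
    frame = Frame(coords=np.vstack([xyz_p, xyz_y + np.asarray(offset)]),
                  box=None if box is None else np.asarray(box))
    return top, frame


class TestRingCog:
    def test_distance_equals_constructed_centroid_separation(self):
        top, frame = _pro_tyr_frame()
        # independent recomputation of both centroids
        names = top.atom_names
        pro_idx = np.flatnonzero(top.atom_residue == 0)
        pro_heavy = [i for i in pro_idx if not names[i].startswith("H")]
        tyr_idx = np.flatnonzero(top.atom_residue == 1)
        ring_names = {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"}
        tyr_ring = [i for i in tyr_idx if names[i] in ring_names]
        expected = np.linalg.norm(
            frame.coords[pro_heavy].mean(axis=0) - frame.coords[tyr_ring].mean(axis=0))
        got = ring_cog_distance(frame, top, ("A", 1), ("B", 1))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_rigid_translation(self):
        top, frame = _pro_tyr_frame()
        d0 = ring_cog_distance(frame, top, ("A", 1), ("B", 1))
        frame2 = Frame(coords=frame.coords + [11.0, -3.0, 40.0])
        assert ring_cog_distance(frame2, top, ("A", 1), ("B", 1)) == pytest.approx(d0)

    def test_wrong_residue_types_rejected(self):
        top, frame = _pro_tyr_frame()
        with pytest.raises(ValidationError):
            ring_cog_distance(frame, top, ("B", 1), ("A", 1))  # swapped

    def test_missing_ring_atom_reported(self):
        ch_y, xyz_y = ck.build_chain("Y", seed=2, chain_id="B")
        del ch_y.residues[0].atoms[-1]  # drop OH
        ch_p, xyz_p = ck.build_chain("P", seed=1, chain_id="A")
        top = Topology([ch_p, ch_y])
        frame = Frame(coords=np.vstack([xyz_p, xyz_y[:-1] + 5.0]))
        with pytest.raises(ValidationError, match="OH"):
            ring_cog_distance(frame, top, ("A", 1), ("B", 1))


def _pair_trajectory(n_frames, box=60.0):
    top, frame0 = _pro_tyr_frame(box=[box] * 3)
    frames = [
        Frame(coords=frame0.coords + 0.01 * k, box=np.full(3, box), time_ps=k * 1000.0)
        for k in range(n_frames)
    ]
    return Trajectory(top, frames)


class TestMasterTrajectory:
    def test_300ns_window_at_10ns_spacing_gives_30_snapshots(self):
        traj = _pair_trajectory(301)
        pairs = [ContactKey("A", 1, "B", 1)]
        master = build_master_trajectory(traj, pairs, 0.0, 300000.0, 10000.0)
        assert len(master) == 30  # end-exclusive snapshot grid

    def test_pooling_scales_with_pair_count(self):
        traj = _pair_trajectory(301)
        pairs = [ContactKey("A", 1, "B", 1)] * 5
        master = build_master_trajectory(traj, pairs, 0.0, 300000.0, 10000.0)
        assert len(master) == 150

    def test_single_frame_window(self):
        traj = _pair_trajectory(3)
        master = build_master_trajectory(
            traj, [ContactKey("A", 1, "B", 1)], 1000.0, 1000.0, 10000.0)
        assert len(master) == 1
        assert master.configurations[0].time_ps == 1000.0

    def test_off_grid_spacing_rejected(self):
        traj = _pair_trajectory(11)
        with pytest.raises(ValidationError):
            build_master_trajectory(traj, [ContactKey("A", 1, "B", 1)], 0.0, 10000.0, 1500.0)

    def test_configuration_separation_uses_nearest_image(self):
        top, _ = _pro_tyr_frame()
        ch_p, xyz_p = ck.build_chain("P", seed=1, chain_id="A")
        ch_y, xyz_y = ck.build_chain("Y", seed=2, chain_id="B")
        # Tyr placed across the periodic boundary
        coords = np.vstack([xyz_p, xyz_y + [58.0, 0, 0]])
        traj = Trajectory(Topology([ch_p, ch_y]),
                          [Frame(coords=coords, box=[60.0, 60.0, 60.0], time_ps=0.0)])
        master = build_master_trajectory(traj, [ContactKey("A", 1, "B", 1)], 0.0, 0.0, 1000.0)
        assert master.configurations[0].separation < 15.0


class TestPairRMSD:
    def test_zero_for_identical_and_rigidly_moved(self, rng):
        a = make_pair_config(rng.normal(size=(6, 3)) * 3)
        assert pair_rmsd(a, a) < 1e-6
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        b = make_pair_config(a.coords @ rot.T + [5.0, 6.0, -2.0])
        assert pair_rmsd(a, b) < 1e-6

    def test_mirror_image_of_chiral_set_is_nonzero(self, chiral_coords):
        a = make_pair_config(chiral_coords)
        mirrored = chiral_coords.copy()
        mirrored[:, 0] *= -1
        b = make_pair_config(mirrored)
        assert pair_rmsd(a, b) > 0.1  # reflections are not allowed

    def test_pseudo_metric_properties_on_sampled_triples(self, rng):
        configs = [make_pair_config(rng.normal(size=(5, 3)) * 2) for _ in range(12)]
        for _ in range(100):
            i, j, k = rng.choice(12, size=3, replace=False)
            dij = pair_rmsd(configs[i], configs[j])
            dji = pair_rmsd(configs[j], configs[i])
            assert dij == pytest.approx(dji, abs=1e-9)
            dik = pair_rmsd(configs[i], configs[k])
            dkj = pair_rmsd(configs[k], configs[j])
            assert dij <= dik + dkj + 1e-9

    def test_template_mismatch_rejected(self, rng):
        a = make_pair_config(rng.normal(size=(5, 3)))
        b = make_pair_config(rng.normal(size=(6, 3)))
        with pytest.raises(ValidationError):
            pair_rmsd(a, b)


def _two_group_master(rng, n_big=7, n_small=3, jitter=0.05):
    base_a = rng.normal(size=(6, 3)) * 3
    base_b = base_a + np.array([15.0, 0.0, 0.0]) + rng.normal(size=(6, 3))
    configs = [
        make_pair_config(base_a, seed_jitter=jitter, rng=rng, separation=4.0)
        for _ in range(n_big)
    ] + [
        make_pair_config(base_b, seed_jitter=jitter, rng=rng, separation=6.5)
        for _ in range(n_small)
    ]
    return MasterTrajectory(configurations=configs, spacing_ps=10000.0)


class TestGromosCluster:
    def test_all_identical_gives_single_full_cluster(self, rng):
        c = make_pair_config(rng.normal(size=(5, 3)))
        master = MasterTrajectory(configurations=[c] * 6, spacing_ps=10000.0)
        result = gromos_cluster(master, 0.5)
        assert len(result.clusters) == 1
        assert result.top_population == 1.0

    def test_two_tight_groups_recovered_with_populations(self, rng):
        master = _two_group_master(rng)
        result = gromos_cluster(master, 1.0)
        assert result.populations[:2] == pytest.approx([0.7, 0.3])

    def test_partition_is_exhaustive_and_populations_sum_to_one(self, rng):
        master = _two_group_master(rng, jitter=0.8)
        for cutoff in (0.3, 0.7, 1.5):
            result = gromos_cluster(master, cutoff)
            all_members = sorted(m for c in result.clusters for m in c["members"])
            assert all_members == list(range(len(master)))
            assert result.populations.sum() == pytest.approx(1.0)

    def test_agrees_with_brute_force_reference(self, rng):
        """Exact agreement with an independent implementation, n <= 20."""
        for trial in range(6):
            n = int(rng.integers(5, 21))
            configs = [make_pair_config(rng.normal(size=(4, 3)) * 1.5) for _ in range(n)]
            mat = rmsd_matrix(configs)
            for cutoff in (0.5, 1.0, 2.0):
                got = gromos_cluster(configs, cutoff, precomputed=mat)
                want = brute_force_gromos(mat, cutoff)
                assert [c["center"] for c in got.clusters] == [c["center"] for c in want]
                assert [c["members"] for c in got.clusters] == [c["members"] for c in want]


class TestOccupancyCurve:
    def test_monotone_in_cutoff_and_saturates(self, rng):
        master = _two_group_master(rng, jitter=0.4)
        curve = occupancy_curve(master, [0.3, 0.5, 0.8, 1.2, 50.0], separation_max_A=20.0)
        pops = [p for _, p in curve]
        assert all(b >= a for a, b in zip(pops, pops[1:]))
        assert pops[-1] == 1.0

    def test_separation_filter_sets_the_denominator(self, rng):
        master = _two_group_master(rng)  # separations 4.0 (7x) and 6.5 (3x)
        curve = occupancy_curve(master, [100.0], separation_max_A=5.0)
        assert curve[0][1] == 1.0  # only the near group enters at all
        result = gromos_cluster(
            [c for c in master.configurations if c.separation < 5.0], 100.0)
        assert len(result.clusters[0]["members"]) == 7

    def test_empty_subset_rejected(self, rng):
        master = _two_group_master(rng)
        with pytest.raises(ValidationError):
            occupancy_curve(master, [0.5], separation_max_A=1.0)


class TestDistanceDistribution:
    def test_all_mass_in_one_bin_for_equal_separations(self, rng):
        c = make_pair_config(rng.normal(size=(4, 3)), separation=4.2)
        master = MasterTrajectory(configurations=[c] * 5, spacing_ps=10000.0)
        hist = distance_distribution(master, bin_width_A=0.5)
        widths = np.diff(hist.bin_edges)
        assert (hist.densities * widths).sum() == pytest.approx(1.0)
        assert (hist.densities > 0).sum() == 1

    def test_bimodal_fixture_shows_two_modes(self, rng):
        configs = [make_pair_config(rng.normal(size=(4, 3)), separation=s)
                   for s in [4.0] * 10 + [6.5] * 10]
        master = MasterTrajectory(configurations=configs, spacing_ps=10000.0)
        hist = distance_distribution(master, bin_width_A=0.5)
        occupied = np.flatnonzero(hist.densities > 0)
        centers = (hist.bin_edges[occupied] + hist.bin_edges[occupied + 1]) / 2
        assert len(occupied) == 2
        assert centers == pytest.approx([4.25, 6.75])
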