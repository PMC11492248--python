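"""Synthetic scene generator: apportionment, placement, planting,
capsid geometry and scripted trajectories."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memscope import (Composition, SurfaceParams, make_capsid_shell,
                      make_membrane_frame, make_trajectory, merge_frames,
                      plant_species_clusters)
from memscope.frame import species_matches
from memscope.scene import UPPER_RATIO


class TestComposition:
    def test_upper_ratio_apportionment_for_1000(self):
        counts = Composition.default_upper().counts(1000)
        assert counts == {"POPC": 250, "DOPC": 250, "POPE": 80, "DOPE": 70,
                          "CHOL": 250, "DPG3": 100}

    @given(st.integers(min_value=len(UPPER_RATIO), max_value=5000))
    def test_apportionment_conserves_total(self, n):
        for comp in (Composition.default_upper(), Composition.default_lower()):
            assert sum(comp.counts(n).values()) == n

    def test_rejects_negative_and_all_zero_ratios(self):
        with pytest.raises(ValueError):
            Composition({"POPC": -1})
        with pytest.raises(ValueError):
            Composition({"POPC": 0, "CHOL": 0})


class TestMembraneFrame:
    def test_flat_surface_places_upper_po4_exactly(self):
        frame, _ = make_membrane_frame(SurfaceParams(c0=50.0),
                                       n_per_leaflet=60,
                                       box=(300, 300, 300), seed=0)
        upper = (frame.molids <= 60) & (frame.names == "PO4")
        assert np.all(frame.coordinates[upper, 2] == 50.0)
        lower = (frame.molids > 60) & (frame.names == "PO4")
        assert np.all(frame.coordinates[lower, 2] == 10.0)

    def test_same_seed_is_bit_identical(self):
        a, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=80,
                                   box=(300, 300, 300), seed=42)
        b, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=80,
                                   box=(300, 300, 300), seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.array_equal(a.species, b.species)
        c, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=80,
                                   box=(300, 300, 300), seed=43)
        assert not np.array_equal(a.coordinates, c.coordinates)

    def test_minimum_in_plane_spacing_is_respected(self):
        frame, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=120,
                                       box=(300, 300, 300), seed=5,
                                       min_spacing=8.0)
        for sel in (frame.molids <= 120, frame.molids > 120):
            xy = frame.coordinates[sel & (frame.names == "PO4"), :2]
            d = xy[:, None, :] - xy[None, :, :]
            for dim in range(2):
                d[:, :, dim] -= 300 * np.round(d[:, :, dim] / 300)
            dist = np.sqrt((d ** 2).sum(axis=2))
            np.fill_diagonal(dist, np.inf)
            assert dist.min() >= 8.0 - 1e-9

    def test_gm3_lipids_carry_a_d_bead(self):
        frame, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=100,
                                       box=(300, 300, 300), seed=1)
        gm3_mols = frame.molecule_ids("GM3")
        assert len(gm3_mols) > 0
        for mol in gm3_mols:
            names = frame.names[frame.molids == mol]
            assert "D" in names

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            make_membrane_frame(SurfaceParams(), box=(0, 300, 300))
        with pytest.raises(ValueError):
            make_membrane_frame(SurfaceParams(), n_per_leaflet=-5)
        with pytest.raises(ValueError):
            # fewer molecules than species in the ratio
            make_membrane_frame(SurfaceParams(), n_per_leaflet=3)
        with pytest.raises(ValueError):
            SurfaceParams(sx=-1.0)


class TestPlantedClusters:
    @pytest.fixture(scope="class")
    def base(self):
        frame, _ = make_membrane_frame(SurfaceParams(), n_per_leaflet=450,
                                       box=(500, 500, 500), seed=9)
        return frame

    def test_truth_has_k_clusters_of_requested_size(self, base):
        _, truth = plant_species_clusters(base, "DPG3", k=2, size=20,
                                          spread=15.0, seed=1)
        assert truth.cluster_sizes() == {0: 20, 1: 20}

    def test_small_blob_below_dbscan_minimum_is_constructible(self, base):
        _, truth = plant_species_clusters(base, "DPG3", k=1, size=4,
                                          spread=10.0, seed=2)
        assert truth.cluster_sizes() == {0: 4}

    def test_blobs_are_separated_beyond_twice_spread_plus_eps(self, base):
        frame, truth = plant_species_clusters(base, "DPG3", k=3, size=8,
                                              spread=14.0, seed=3)
        # brute-force scan over all inter-blob member pairs
        xy = {}
        for mol, lab in truth.planted_cluster_labels.items():
            if lab < 0:
                continue
            sel = (frame.molids == mol) & (frame.names == "PO4")
            xy.setdefault(lab, []).append(frame.coordinates[sel][0, :2])
        min_inter = np.inf
        labs = sorted(xy)
        for i in labs:
            for j in labs:
                if j <= i:
                    continue
                for p in xy[i]:
                    for q in xy[j]:
                        min_inter = min(min_inter, np.linalg.norm(p - q))
        assert min_inter > 56.0

    def test_impossible_packing_raises(self, base):
        with pytest.raises(ValueError):
            plant_species_clusters(base, "DPG3", k=2, size=200, spread=15.0)
        with pytest.raises(ValueError):
            plant_species_clusters(base, "DPG3", k=1, size=5, spread=-1.0)


class TestCapsidShell:
    def test_beads_lie_exactly_on_the_sphere(self):
        shell = make_capsid_shell(center=(10, 20, 30), radius=125.0,
                                  beads_per_face=20, seed=0)
        r = np.linalg.norm(shell.coordinates - np.array([10, 20, 30.0]),
                           axis=1)
        assert np.max(np.abs(r - 125.0)) < 1e-6

    def test_diameter_spans_most_of_the_sphere(self):
        shell = make_capsid_shell(radius=125.0, beads_per_face=20, seed=1)
        from scipy.spatial.distance import pdist
        dmax = pdist(shell.coordinates).max()
        assert 0.95 * 250.0 <= dmax <= 250.0 + 1e-9

    def test_pentamer_labels_partition_into_12_groups(self):
        shell = make_capsid_shell(beads_per_face=7, seed=2)
        groups, counts = np.unique(shell.molids, return_counts=True)
        assert len(groups) == 12
        assert np.all(counts == 7)

    def test_degenerate_arguments_raise(self):
        with pytest.raises(ValueError):
            make_capsid_shell(beads_per_face=0)
        with pytest.raises(ValueError):
            make_capsid_shell(radius=-5.0)


class TestTrajectory:
    def test_constant_schedules_reproduce_the_base_frame(self, capsid_scene,
                                                         flat_surface):
        frames, _ = make_trajectory(
            capsid_scene, 5, rotation_schedule=[0.0] * 5,
            dimple_schedule=[flat_surface] * 5, seed=0)
        for fr in frames:
            assert np.allclose(fr.coordinates, capsid_scene.coordinates,
                               atol=1e-9)
        times = [fr.time for fr in frames]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_rigid_rotation_preserves_intracapsid_distances(self,
                                                            capsid_scene):
        frames, _ = make_trajectory(
            capsid_scene, 3, rotation_schedule=[0.0, 45.0, 170.0],
            rotation_axis=(1.0, 2.0, 0.5), seed=0)
        cap0 = frames[0].coordinates[species_matches(frames[0].species,
                                                     "CAPS")]
        for fr in frames[1:]:
            cap = fr.coordinates[species_matches(fr.species, "CAPS")]
            from scipy.spatial.distance import pdist
            assert np.max(np.abs(pdist(cap) - pdist(cap0))) < 1e-6

    def test_mismatched_schedule_length_raises(self, capsid_scene):
        with pytest.raises(ValueError):
            make_trajectory(capsid_scene, 4, rotation_schedule=[0.0] * 3)
        with pytest.raises(ValueError):
            make_trajectory(capsid_scene, 4,
                            dimple_schedule=[SurfaceParams()] * 5)

    def test_fixed_seed_trajectories_are_bit_identical(self, capsid_scene,
                                                       flat_surface):
        kw = dict(n_frames=4, rotation_schedule=[0, 10, 20, 30.0],
                  dimple_schedule=[flat_surface] * 4, z_noise_sd=0.5)
        a, _ = make_trajectory(capsid_scene, seed=5, **kw)
        b, _ = make_trajectory(capsid_scene, seed=5, **kw)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.coordinates, fb.coordinates)
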