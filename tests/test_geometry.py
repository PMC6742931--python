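"""Volumes, liminal volumes, transition matrices: examples and oracles."""

import numpy as np
import pytest

from sementropy import (
    LabeledVolume,
    PhantomSpec,
    adjacency_components,
    generate_phantom,
    initial_distribution,
    liminal_volumes,
    merge_tags,
    region_volumes,
    transition_matrix,
)
from sementropy.errors import NoTaggedVoxelsError

from conftest import brute_force_liminal


class TestRegionVolumes:
    def test_slab_volumes(self, slab_volume):
        assert region_volumes(slab_volume) == {"A": 32.0, "B": 32.0}

    def test_anisotropic_spacing_scales_volume(self, slab_volume):
        vol = LabeledVolume(slab_volume.labels, (0.5, 1, 1), slab_volume.tag_map)
        assert region_volumes(vol) == {"A": 16.0, "B": 16.0}

    def test_absent_tag_reported_zero_with_warning(self, slab_volume):
        vol = LabeledVolume(slab_volume.labels, (1, 1, 1),
                            {**slab_volume.tag_map, 9: "ghost"})
        with pytest.warns(UserWarning, match="ghost"):
            vols = region_volumes(vol)
        assert vols["ghost"] == 0.0

    def test_all_background_rejected(self):
        vol = LabeledVolume(np.zeros((3, 3, 3), dtype=np.int32), tag_map={})
        with pytest.raises(NoTaggedVoxelsError, match="no tagged voxels"):
            region_volumes(vol)

    def test_volume_conservation(self):
        vol = generate_phantom(PhantomSpec(kind="voronoi", shape=(8, 8, 8),
                                           params={"m": 5}, seed=3))
        total = sum(region_volumes(vol).values())
        assert total == float(np.count_nonzero(vol.labels)) * vol.voxel_volume


class TestInitialDistribution:
    @pytest.mark.parametrize(
        "volumes,expected_tags,expected_p",
        [
            ({"A": 32, "B": 32}, ["A", "B"], [0.5, 0.5]),
            ({"A": 16, "B": 48}, ["A", "B"], [0.25, 0.75]),
        ],
    )
    def test_volume_fractions(self, volumes, expected_tags, expected_p):
        tags, p = initial_distribution(volumes)
        assert tags == expected_tags
        assert p == pytest.approx(expected_p)

    def test_zero_volume_tag_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-volume"):
            tags, p = initial_distribution({"A": 10, "B": 0, "C": 30})
        assert tags == ["A", "C"]
        assert p == pytest.approx([0.25, 0.75])

    def test_scale_invariance_under_voxel_replication(self, thin_plane_volume):
        """Doubling the grid along every axis leaves the fractions unchanged."""
        _, p1 = initial_distribution(region_volumes(thin_plane_volume))
        big = LabeledVolume(
            np.repeat(np.repeat(np.repeat(thin_plane_volume.labels, 2, 0), 2, 1), 2, 2),
            tag_map=thin_plane_volume.tag_map,
        )
        _, p2 = initial_distribution(region_volumes(big))
        assert np.array_equal(p1, p2)


class TestLiminalVolumes:
    def test_slab_phantom_worked_example(self, slab_volume):
        table = liminal_volumes(slab_volume, k=1, connectivity="face")
        assert table.tags == ["A", "B"]
        assert table.v.tolist() == [[16.0, 16.0], [16.0, 16.0]]
        assert table.clamped == set()

    def test_thin_plane_worked_example(self, thin_plane_volume):
        table = liminal_volumes(thin_plane_volume)
        assert table.tags == ["A", "B"]
        # A is entirely liminal toward B; B keeps a 2-plane interior
        assert table.v.tolist() == [[0.0, 16.0], [16.0, 32.0]]

    def test_single_tag_volume(self):
        vol = LabeledVolume(np.ones((3, 3, 3), dtype=np.int32), tag_map={1: "A"})
        table = liminal_volumes(vol)
        assert table.tags == ["A"] and table.v.tolist() == [[27.0]]

    @pytest.mark.parametrize("bad_k", [0, -1, 1.5])
    def test_invalid_dilation_amount(self, slab_volume, bad_k):
        with pytest.raises(ValueError):
            liminal_volumes(slab_volume, k=bad_k)

    def test_interface_symmetry_on_flat_boundary(self, slab_volume):
        """With k=1 each side of a flat interface contributes one voxel layer."""
        table = liminal_volumes(slab_volume, k=1, connectivity="face")
        assert table.v[0, 1] == table.v[1, 0]

    def test_diagonal_clamped_for_thin_region(self):
        # a 1-voxel plane between two neighbours is liminal toward both
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[:, :, 0], labels[:, :, 1], labels[:, :, 2] = 1, 2, 3
        vol = LabeledVolume(labels, tag_map={1: "A", 2: "B", 3: "C"})
        with pytest.warns(UserWarning, match="clamped"):
            table = liminal_volumes(vol)
        i = table.tags.index("B")
        assert "B" in table.clamped and table.v[i, i] == 0.0

    @pytest.mark.parametrize("connectivity", ["face", "edge", "vertex"])
    def test_matches_brute_force_neighbourhood_scan(self, connectivity):
        """Dilation-based liminal volumes equal the pure-Python voxel-set oracle."""
        rng = np.random.default_rng(7)
        for trial in range(5):
            vol = generate_phantom(
                PhantomSpec(kind="voronoi", shape=(10, 10, 10),
                            params={"m": int(rng.integers(3, 8))}, seed=trial)
            )
            table = liminal_volumes(vol, k=1, connectivity=connectivity)
            otags, ov = brute_force_liminal(vol, k=1, connectivity=connectivity)
            assert table.tags == otags
            np.testing.assert_array_equal(table.v, ov)

    def test_k2_matches_brute_force(self):
        vol = generate_phantom(PhantomSpec(kind="voronoi", shape=(8, 8, 8),
                                           params={"m": 4}, seed=11))
        table = liminal_volumes(vol, k=2)
        otags, ov = brute_force_liminal(vol, k=2)
        assert table.tags == otags
        np.testing.assert_array_equal(table.v, ov)


class TestTransitionMatrix:
    def test_slab_transition_matrix(self, slab_volume):
        model = transition_matrix(liminal_volumes(slab_volume),
                                  volumes=region_volumes(slab_volume))
        assert model.Q.tolist() == [[0.5, 0.5], [0.5, 0.5]]
        assert model.p0.tolist() == [0.5, 0.5]

    def test_thin_plane_transition_matrix(self, thin_plane_volume):
        model = transition_matrix(liminal_volumes(thin_plane_volume),
                                  volumes=region_volumes(thin_plane_volume))
        assert model.Q[0].tolist() == [0.0, 1.0]
        assert model.Q[1] == pytest.approx([1 / 3, 2 / 3])
        assert model.p0 == pytest.approx([0.25, 0.75])

    def test_single_tag_model(self):
        vol = LabeledVolume(np.ones((2, 2, 2), dtype=np.int32), tag_map={1: "A"})
        model = transition_matrix(liminal_volumes(vol))
        assert model.Q.tolist() == [[1.0]]

    def test_rows_stochastic_on_random_phantoms(self):
        for seed in range(3):
            vol = generate_phantom(PhantomSpec(kind="voronoi", shape=(12, 12, 12),
                                               params={"m": 10}, seed=seed))
            model = transition_matrix(liminal_volumes(vol),
                                      volumes=region_volumes(vol))
            np.testing.assert_allclose(model.Q.sum(axis=1), 1.0, atol=1e-12)
            assert (model.Q >= 0).all()

    def test_zero_row_rejected(self):
        from sementropy.geometry import LiminalVolumeTable
        table = LiminalVolumeTable(tags=["A", "B"],
                                   v=np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="B"):
            transition_matrix(table)


class TestAdjacencyComponents:
    def test_slab_single_component(self, slab_volume):
        model = transition_matrix(liminal_volumes(slab_volume))
        assert adjacency_components(model) == [{"A", "B"}]

    def test_islands_give_two_components(self, two_island_volume):
        model = transition_matrix(liminal_volumes(two_island_volume))
        comps = adjacency_components(model)
        assert sorted(map(sorted, comps)) == [["A"], ["B"]]

    def test_thin_plane_single_component(self, thin_plane_volume):
        model = transition_matrix(liminal_volumes(thin_plane_volume))
        assert adjacency_components(model) == [{"A", "B"}]


class TestMergeTags:
    def test_full_merge_yields_single_tag(self, slab_volume):
        merged = merge_tags(slab_volume, [{"A", "B"}])
        assert set(merged.tag_map.values()) == {"A+B"}
        assert np.count_nonzero(merged.labels) == 64

    def test_singleton_group_is_identity_up_to_relabelling(self, slab_volume):
        merged = merge_tags(slab_volume, [{"A"}])
        assert set(merged.tag_map.values()) == {"A", "B"}
        for tag in ("A", "B"):
            before = region_volumes(slab_volume)[tag]
            assert region_volumes(merged)[tag] == before

    def test_volume_conservation(self, stripe3_volume):
        merged = merge_tags(stripe3_volume, [{"A", "B"}])
        vols = region_volumes(merged)
        assert vols["A+B"] == 8.0 and vols["C"] == 4.0

    def test_overlapping_groups_rejected(self, stripe3_volume):
        with pytest.raises(ValueError, match="overlapping"):
            merge_tags(stripe3_volume, [{"A", "B"}, {"B", "C"}])

    def test_unknown_tag_rejected(self, stripe3_volume):
        with pytest.raises(ValueError, match="unknown"):
            merge_tags(stripe3_volume, [{"A", "Z"}])
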