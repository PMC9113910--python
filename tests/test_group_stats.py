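import numpy as np
import pytest
from scipy import stats

from alffkit.group_stats import TestConfig, cluster_threshold, label_clusters, paired_t, two_sample_t
from alffkit.io_core import BrainMask, LabelAtlas, StatMap
from conftest import flood_fill_components

SHAPE = (6, 5, 4)


def make_mask(shape=SHAPE):
    return BrainMask(data=np.ones(shape, dtype=bool), affine=np.diag((6.0, 6.0, 10.0, 1.0)))


def stat_maps(t_data, p_data, mask):
    affine = mask.affine
    return (
        StatMap(data=t_data, kind="t", affine=affine, mask=mask),
        StatMap(data=p_data, kind="p", affine=affine, mask=mask),
    )


class TestTwoSampleT:
    def test_identical_groups_give_null_result(self, rng):
        mask = make_mask()
        a = rng.normal(size=(5, *SHAPE))
        t_map, p_map = two_sample_t(a, a.copy(), mask)
        np.testing.assert_allclose(t_map.data[mask.data], 0.0, atol=1e-12)
        np.testing.assert_allclose(p_map.data[mask.data], 1.0, atol=1e-12)

    def test_matches_reference_routine_per_voxel(self, rng):
        mask = make_mask()
        a = rng.normal(size=(8, *SHAPE))
        b = rng.normal(0.3, 1.2, size=(11, *SHAPE))
        t_map, p_map = two_sample_t(a, b, mask)
        ref_t, ref_p = stats.ttest_ind(a, b, axis=0, equal_var=True)
        np.testing.assert_allclose(t_map.data, ref_t, atol=1e-10)
        np.testing.assert_allclose(p_map.data, ref_p, atol=1e-10)

    def test_null_type_one_error_within_binomial_bounds(self, rng):
        mask = BrainMask(data=np.ones((10, 10, 10), dtype=bool), affine=np.eye(4))
        a = rng.normal(size=(20, 10, 10, 10))
        b = rng.normal(size=(20, 10, 10, 10))
        _, p_map = two_sample_t(a, b, mask)
        frac = (p_map.data < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_degenerate_variance_voxel_gets_p_one(self):
        mask = make_mask((2, 2, 2))
        a = np.ones((4, 2, 2, 2))
        b = np.ones((4, 2, 2, 2))
        t_map, p_map = two_sample_t(a, b, mask)
        assert (p_map.data == 1.0).all()

    def test_single_subject_group_rejected(self, rng):
        mask = make_mask()
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_t(rng.normal(size=(1, *SHAPE)), rng.normal(size=(5, *SHAPE)), mask)


class TestPairedT:
    def test_constant_shift_gives_floor_p(self, rng):
        # exact-representable maps so the differences carry no float residue
        mask = make_mask()
        before = rng.integers(0, 8, size=(6, *SHAPE)).astype(float) / 4.0
        after = before + 2.0
        t_map, p_map = paired_t(before, after, mask)
        assert np.all(np.isinf(t_map.data[mask.data]))
        assert np.all(t_map.data[mask.data] > 0)
        assert np.all(p_map.data[mask.data] == 0.0)

    def test_matches_reference_routine(self, rng):
        mask = make_mask()
        before = rng.normal(size=(9, *SHAPE))
        after = before + rng.normal(0.1, 0.5, size=(9, *SHAPE))
        t_map, p_map = paired_t(before, after, mask)
        ref_t, ref_p = stats.ttest_rel(after, before, axis=0)
        np.testing.assert_allclose(t_map.data, ref_t, atol=1e-10)
        np.testing.assert_allclose(p_map.data, ref_p, atol=1e-10)

    def test_null_type_one_error_calibrated(self, rng):
        mask = BrainMask(data=np.ones((12, 12, 8), dtype=bool), affine=np.eye(4))
        before = rng.normal(size=(15, 12, 12, 8))
        after = before + rng.normal(size=(15, 12, 12, 8))  # zero mean shift
        _, p_map = paired_t(before, after, mask)
        frac = (p_map.data < 0.05).mean()
        assert 0.02 < frac < 0.08

    def test_differs_from_unpaired_on_correlated_data(self, rng):
        mask = make_mask()
        subject_effect = rng.normal(0, 3.0, size=(10, 1, 1, 1))
        before = subject_effect + rng.normal(size=(10, *SHAPE))
        after = before + 0.5 + 0.2 * rng.normal(size=(10, *SHAPE))
        t_pair, _ = paired_t(before, after, mask)
        t_unpair, _ = two_sample_t(after, before, mask)
        # shared subject effects cancel in pairing: paired t is larger
        assert np.abs(t_pair.data[mask.data]).mean() > np.abs(t_unpair.data[mask.data]).mean()

    def test_length_mismatch_rejected(self, rng):
        mask = make_mask()
        with pytest.raises(ValueError, match="matched"):
            paired_t(rng.normal(size=(5, *SHAPE)), rng.normal(size=(6, *SHAPE)), mask)


class TestClusterThreshold:
    def maps_from_binary(self, supra, t_sign=1.0):
        mask = make_mask(supra.shape)
        t = np.where(supra, t_sign * 5.0, 0.0).astype(float)
        p = np.where(supra, 1e-6, 0.5).astype(float)
        return stat_maps(t, p, mask)

    def test_extent_rule_is_strict(self):
        supra = np.zeros((10, 10, 10), dtype=bool)
        supra[0:6, 0:6, 0] = True  # 36 voxels exactly
        t_map, p_map = self.maps_from_binary(supra)
        table = cluster_threshold(t_map, p_map, TestConfig(extent=36))
        assert len(table) == 0
        table35 = cluster_threshold(t_map, p_map, TestConfig(extent=35))
        assert len(table35) == 1 and table35.iloc[0]["size_voxels"] == 36

    def test_sizes_40_and_10_keep_only_large(self):
        supra = np.zeros((12, 12, 6), dtype=bool)
        supra[0:4, 0:5, 0:2] = True  # 40 voxels
        supra[8:10, 8:13, 5] = True  # 10 voxels (clipped to grid: 2x4x1=8... keep separate)
        supra[8:10, 7:12, 5] = True
        t_map, p_map = self.maps_from_binary(supra)
        table = cluster_threshold(t_map, p_map, TestConfig(extent=36))
        assert len(table) == 1
        assert table.iloc[0]["size_voxels"] == 40

    def test_full_cube_single_cluster(self):
        supra = np.ones((5, 5, 5), dtype=bool)
        t_map, p_map = self.maps_from_binary(supra)
        table = cluster_threshold(t_map, p_map, TestConfig(extent=36))
        assert len(table) == 1
        assert table.iloc[0]["size_voxels"] == 125

    def test_sign_split_separates_increase_decrease(self):
        supra = np.zeros((8, 8, 8), dtype=bool)
        supra[0:3, 0:3, 0:3] = True
        supra[5:8, 5:8, 5:8] = True
        t = np.zeros((8, 8, 8))
        t[0:3, 0:3, 0:3] = 4.0
        t[5:8, 5:8, 5:8] = -4.0
        p = np.where(supra, 1e-6, 0.5)
        mask = make_mask((8, 8, 8))
        t_map, p_map = stat_maps(t, p, mask)
        table = cluster_threshold(t_map, p_map, TestConfig(extent=0))
        assert sorted(table["sign"]) == ["decrease", "increase"]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(30):
            supra = rng.random((9, 9, 9)) < 0.35
            t_map, p_map = self.maps_from_binary(supra)
            table = cluster_threshold(
                t_map, p_map, TestConfig(extent=0, connectivity=connectivity)
            )
            oracle = flood_fill_components(supra, connectivity)
            assert sorted(table["size_voxels"]) == sorted(len(c) for c in oracle)
            assert table["size_voxels"].sum() == supra.sum()

    def test_raising_extent_never_adds_clusters(self, rng):
        supra = rng.random((10, 10, 10)) < 0.4
        t_map, p_map = self.maps_from_binary(supra)
        counts = [
            len(cluster_threshold(t_map, p_map, TestConfig(extent=e)))
            for e in (0, 5, 10, 20, 40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_by_size_then_peak_t(self):
        supra = np.zeros((12, 12, 4), dtype=bool)
        supra[0:2, 0:2, 0] = True  # 4 voxels
        supra[6:9, 6:9, 0] = True  # 9 voxels
        t = np.where(supra, 3.0, 0.0)
        p = np.where(supra, 1e-6, 0.5)
        mask = make_mask((12, 12, 4))
        table = cluster_threshold(*stat_maps(t, p, mask), TestConfig(extent=0))
        assert list(table["size_voxels"]) == [9, 4]
        assert list(table["cluster_id"]) == [1, 2]


class TestLabelClusters:
    def build_table_and_atlas(self):
        supra = np.zeros((8, 8, 4), dtype=bool)
        supra[1:4, 1:4, 1:3] = True
        t = np.where(supra, 5.0, 0.0)
        p = np.where(supra, 1e-6, 0.5)
        mask = make_mask((8, 8, 4))
        table = cluster_threshold(*stat_maps(t, p, mask), TestConfig(extent=0))
        atlas_data = np.zeros((8, 8, 4), dtype=np.int32)
        atlas_data[0:5, 0:5, :] = 3
        atlas = LabelAtlas(data=atlas_data, names={3: "precuneus"}, affine=mask.affine)
        return table, atlas

    def test_peak_inside_region_gets_its_name(self):
        table, atlas = self.build_table_and_atlas()
        labeled = label_clusters(table, atlas)
        assert labeled.iloc[0]["region_label"] == "precuneus"

    def test_background_peak_unlabeled(self):
        table, atlas = self.build_table_and_atlas()
        atlas.data[:] = 0
        labeled = label_clusters(table, atlas)
        assert labeled.iloc[0]["region_label"] == "unlabeled"

    def test_renaming_atlas_changes_names_not_sizes(self):
        table, atlas = self.build_table_and_atlas()
        renamed = LabelAtlas(
            data=atlas.data, names={3: "insula"}, affine=atlas.affine
        )
        l1 = label_clusters(table, atlas)
        l2 = label_clusters(table, renamed)
        assert list(l1["size_voxels"]) == list(l2["size_voxels"])
        assert l2.iloc[0]["region_label"] == "insula"
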