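"""Vessel-mask operations: fusion, downsampling, splitting, shells."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, distance_transform_cdt

from vasconn.grid import GridMismatchError, VesselLabelMap, VolumeGrid
from vasconn.masks import (
    MaskError,
    combine_segmentations,
    downsample_mask,
    make_shells,
    restrict_to_gm,
    split_by_label,
    structuring_element,
)

from conftest import mask_from_array


def random_mask(rng, shape=(8, 8, 8), p=0.3):
    return mask_from_array(rng.random(shape) < p)


class TestCombine:
    def test_idempotent(self, rng):
        m = random_mask(rng)
        assert np.array_equal(combine_segmentations([m, m]).data, m.data)

    def test_union_of_disjoint_singletons(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        fused = combine_segmentations([mask_from_array(a), mask_from_array(b)])
        assert fused.n_true == 2

    def test_matches_logical_or_oracle(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        expected = masks[0].data | masks[1].data | masks[2].data
        assert np.array_equal(combine_segmentations(masks).data, expected)

    def test_commutative_and_associative(self, rng):
        a, b, c = (random_mask(rng) for _ in range(3))
        ab_c = combine_segmentations([combine_segmentations([a, b]), c])
        c_ba = combine_segmentations([c, combine_segmentations([b, a])])
        assert np.array_equal(ab_c.data, c_ba.data)

    def test_grid_mismatch_names_offender(self, rng):
        a = random_mask(rng, shape=(8, 8, 8))
        b = random_mask(rng, shape=(6, 6, 6))
        with pytest.raises(GridMismatchError, match="#1"):
            combine_segmentations([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(MaskError):
            combine_segmentations([])


class TestDownsample:
    def target(self, shape=(2, 2, 2), mm=8.0):
        return VolumeGrid.from_spacing(shape, (mm,) * 3)

    def test_full_block_true_at_any_occupancy(self):
        src = mask_from_array(np.ones((4, 4, 4), bool))
        for occ in (None, 0.5, 1.0):
            out = downsample_mask(src, self.target(), occ)
            assert out.data.all()

    def test_partial_block_thresholds(self):
        # one 2x2x2 block with 5/8 true -> fraction 0.625
        arr = np.zeros((2, 2, 2), bool)
        arr.ravel()[:5] = True
        src = mask_from_array(arr)
        tgt = self.target(shape=(1, 1, 1))
        assert downsample_mask(src, tgt, 0.5).data.all()
        assert not downsample_mask(src, tgt, 0.75).data.any()

    def test_empty_stays_empty(self):
        src = mask_from_array(np.zeros((4, 4, 4), bool))
        assert downsample_mask(src, self.target()).is_empty()

    def test_antitone_in_occupancy_min(self, rng):
        src = random_mask(rng, shape=(8, 8, 8), p=0.5)
        tgt = VolumeGrid.from_spacing((4, 4, 4), (8.0,) * 3)
        prev = downsample_mask(src, tgt, 0.25).data
        for occ in (0.5, 0.75, 1.0):
            cur = downsample_mask(src, tgt, occ).data
            assert (cur <= prev).all()  # higher threshold -> subset
            prev = cur

    def test_any_policy_keeps_single_voxel_vessel(self):
        arr = np.zeros((4, 4, 4), bool)
        arr[1, 2, 3] = True
        out = downsample_mask(mask_from_array(arr), self.target())
        assert out.n_true == 1

    def test_non_nested_grids_rejected(self):
        src = mask_from_array(np.ones((5, 4, 4), bool))
        with pytest.raises(MaskError, match="axis 0"):
            downsample_mask(src, self.target())

    def test_finer_target_rejected(self):
        src = mask_from_array(np.ones((4, 4, 4), bool), voxel_mm=8.0)
        fine = VolumeGrid.from_spacing((8, 8, 8), (4.0,) * 3)
        with pytest.raises(MaskError):
            downsample_mask(src, fine)


class TestSplitAndRestrict:
    def labels_from(self, mask_arr, artery_sel):
        lab = np.zeros(mask_arr.shape, np.int16)
        lab[mask_arr] = 2
        lab[artery_sel] = 1
        grid = VolumeGrid.from_spacing(mask_arr.shape, (4.0,) * 3)
        return VesselLabelMap(grid, lab)

    def test_partition_counts(self):
        arr = np.zeros((5, 5, 5), bool)
        arr.ravel()[:10] = True
        art_sel = np.zeros_like(arr)
        art_sel.ravel()[:6] = True
        labels = self.labels_from(arr, art_sel)
        artery, vein = split_by_label(mask_from_array(arr), labels)
        assert (artery.n_true, vein.n_true) == (6, 4)

    def test_all_vein_gives_empty_artery(self):
        arr = np.zeros((5, 5, 5), bool)
        arr.ravel()[:4] = True
        labels = self.labels_from(arr, np.zeros_like(arr))
        artery, vein = split_by_label(mask_from_array(arr), labels)
        assert artery.is_empty() and vein.n_true == 4

    def test_random_labeling_is_partition(self, rng):
        arr = rng.random((8, 8, 8)) < 0.3
        art_sel = arr & (rng.random((8, 8, 8)) < 0.5)
        labels = self.labels_from(arr, art_sel)
        artery, vein = split_by_label(mask_from_array(arr), labels)
        assert np.array_equal(artery.data | vein.data, arr)
        assert not (artery.data & vein.data).any()

    def test_unlabeled_voxel_error_lists_coordinates(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 3, 4] = True
        labels = self.labels_from(np.zeros_like(arr), np.zeros_like(arr))
        with pytest.raises(MaskError, match=r"\(2, 3, 4\)"):
            split_by_label(mask_from_array(arr), labels)

    def test_restrict_subset_unchanged(self, rng):
        gm = random_mask(rng, p=0.8)
        sub = mask_from_array(gm.data & (rng.random((8, 8, 8)) < 0.3))
        assert np.array_equal(restrict_to_gm(sub, gm).data, sub.data)

    def test_restrict_disjoint_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[2] = True, True
        assert restrict_to_gm(mask_from_array(a), mask_from_array(b)).is_empty()

    def test_restrict_matches_logical_and(self, rng):
        m, gm = random_mask(rng), random_mask(rng, p=0.5)
        assert np.array_equal(restrict_to_gm(m, gm).data, m.data & gm.data)


class TestShells:
    def single_voxel(self, shape=(9, 9, 9)):
        arr = np.zeros(shape, bool)
        arr[4, 4, 4] = True
        return mask_from_array(arr)

    def test_single_voxel_26conn_shell_sizes(self):
        # (2k+1)^3 - (2k-1)^3 voxels at Chebyshev distance k
        ss = make_shells(self.single_voxel(), K=3, connectivity=26)
        assert [s.n_true for s in ss.shells] == [26, 98, 218]

    def test_single_voxel_6conn_first_shell(self):
        ss = make_shells(self.single_voxel(), K=1, connectivity=6)
        assert ss.shells[0].n_true == 6

    @pytest.mark.parametrize("connectivity,metric", [(6, "taxicab"), (26, "chessboard")])
    def test_random_mask_matches_distance_transform(self, rng, connectivity, metric):
        mask = random_mask(rng, shape=(10, 10, 8), p=0.08)
        if mask.is_empty():
            pytest.skip("degenerate draw")
        ss = make_shells(mask, K=3, connectivity=connectivity)
        dist = distance_transform_cdt(~mask.data, metric=metric)
        for k in range(1, 4):
            assert np.array_equal(ss.shell(k).data, np.asarray(dist) == k)

    def test_shells_disjoint_from_each_other_and_source(self, rng):
        mask = random_mask(rng, shape=(10, 10, 8), p=0.1)
        ss = make_shells(mask, K=3, connectivity=26)
        combined = mask.data.copy()
        for s in ss.shells:
            assert not (s.data & combined).any()
            combined |= s.data

    def test_union_equals_k_fold_dilation(self, rng):
        mask = random_mask(rng, shape=(10, 10, 8), p=0.1)
        K = 3
        ss = make_shells(mask, K=K, connectivity=18)
        union = mask.data.copy()
        for s in ss.shells:
            union |= s.data
        dil = mask.data.copy()
        for _ in range(K):
            dil = binary_dilation(dil, structure=structuring_element(18))
        assert np.array_equal(union, dil)

    def test_exclusion_removes_vessel_voxels(self):
        arr = np.zeros((9, 9, 9), bool)
        arr[4, 4, 4] = True
        other = np.zeros_like(arr)
        other[4, 4, 5] = True  # a vein voxel adjacent to the artery
        ss = make_shells(
            mask_from_array(arr), K=1, connectivity=26,
            exclude=mask_from_array(arr | other),
        )
        assert ss.shells[0].n_true == 25
        assert not ss.shells[0].data[4, 4, 5]

    def test_empty_mask_rejected(self):
        with pytest.raises(MaskError):
            make_shells(mask_from_array(np.zeros((5, 5, 5), bool)), K=1)

    def test_empty_shell_warns(self):
        # mask filling the whole grid leaves nowhere to dilate into
        with pytest.warns(UserWarning, match="empty"):
            make_shells(mask_from_array(np.ones((4, 4, 4), bool)), K=1)
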