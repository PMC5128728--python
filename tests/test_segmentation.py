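"""Threshold, 26-connected labeling (vs a flood-fill oracle), watershed."""

import numpy as np
import pytest

from chromovol import segmentation
from chromovol.segmentation import SegmentationParams, label_components, separate_objects
from chromovol.volume_io import VoxelGrid

SPACING = (100.0, 100.0, 100.0)


def flood_fill_components(mask):
    """Reference 26-connected partition: set of frozensets of voxel coords."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    comps = set()
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[k] < mask.shape[k] for k in range(3)):
                    if mask[w] and not visited[w]:
                        visited[w] = True
                        stack.append(w)
        comps.add(frozenset(comp))
    return comps


class TestLabelComponentsOracle:
    def test_matches_flood_fill_on_1000_random_masks(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            shape = tuple(rng.integers(1, 6, size=3))
            mask = rng.random(shape) < rng.uniform(0.1, 0.9)
            lv = label_components(mask, SPACING)
            got = {
                frozenset(map(tuple, np.argwhere(lv.labels == i)))
                for i in range(1, lv.n_labels + 1)
            }
            assert got == flood_fill_components(mask)

    def test_corner_touch_is_one_object(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert label_components(mask, SPACING).n_labels == 1

    def test_labels_sorted_by_descending_size(self):
        mask = np.zeros((3, 9, 9), dtype=bool)
        mask[1, 0:2, 0:2] = True    # 4 voxels
        mask[1, 5:8, 5:8] = True    # 9 voxels
        lv = label_components(mask, SPACING)
        vols = lv.volumes_um3()
        assert vols[0] > vols[1]

    def test_empty_mask(self):
        assert label_components(np.zeros((4, 4, 4), dtype=bool), SPACING).n_labels == 0


def two_sphere_mask(gap_vox=12, radius=8, shape=(24, 24, 40)):
    zz, yy, xx = np.indices(shape)
    c = np.array(shape) / 2.0 - 0.5
    a = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - (c[2] - gap_vox / 2)) ** 2 <= radius**2
    b = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - (c[2] + gap_vox / 2)) ** 2 <= radius**2
    return a | b


class TestSeparateObjects:
    def test_touching_spheres_split_with_small_h(self):
        mask = two_sphere_mask()
        assert label_components(mask, SPACING).n_labels == 1
        # the discrete saddle depth is ~1.9 voxels for these spheres
        lv = separate_objects(mask, SPACING, SegmentationParams(h=1.5))
        assert lv.n_labels == 2

    def test_large_h_keeps_component_whole(self):
        mask = two_sphere_mask()
        lv = separate_objects(mask, SPACING, SegmentationParams(h=7.0))
        assert lv.n_labels == 1

    def test_label_count_non_increasing_in_h(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((20, 40, 40), dtype=bool)
        zz, yy, xx = np.indices(mask.shape)
        for _ in range(6):
            c = rng.uniform(6, [14, 34, 34])
            r = rng.uniform(4, 7)
            mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        counts = [
            separate_objects(mask, SPACING, SegmentationParams(h=h)).n_labels
            for h in (1.0, 3.0, 5.0, 7.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_never_merges_and_never_drops(self):
        rng = np.random.default_rng(9)
        mask = np.zeros((16, 32, 32), dtype=bool)
        zz, yy, xx = np.indices(mask.shape)
        for _ in range(5):
            c = rng.uniform(4, [12, 28, 28])
            mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= rng.uniform(2, 5) ** 2
        comps = label_components(mask, SPACING)
        out = separate_objects(mask, SPACING, SegmentationParams(h=2.0))
        # same foreground, and every output label inside exactly one component
        assert np.array_equal(out.labels > 0, mask)
        for i in range(1, out.n_labels + 1):
            assert len(np.unique(comps.labels[out.labels == i])) == 1
        assert out.n_labels >= comps.n_labels


class TestThreshold:
    def test_otsu_on_constant_image_is_an_error(self):
        grid = VoxelGrid(data=np.full((4, 4, 4), 7, dtype=np.uint8), spacing_nm=SPACING)
        with pytest.raises(ValueError, match="constant"):
            segmentation.threshold(grid, SegmentationParams())

    def test_manual_threshold_inverted(self):
        data = np.full((4, 4, 4), 200, dtype=np.uint8)
        data[1, 1, 1] = 50
        grid = VoxelGrid(data=data, spacing_nm=SPACING)
        mask, t = segmentation.threshold(
            grid, SegmentationParams(threshold_mode="manual", threshold_value=100.0)
        )
        assert t == 100.0
        assert mask.sum() == 1 and mask[1, 1, 1]

    def test_manual_without_value_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold_mode="manual").validate()

    def test_bad_h_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(h=0.0).validate()


class TestFilterSmall:
    def test_small_labels_dropped_and_ids_recompacted(self):
        mask = np.zeros((3, 9, 9), dtype=bool)
        mask[1, 0:2, 0:2] = True
        mask[1, 5:8, 5:8] = True
        lv = label_components(mask, SPACING)
        voxvol = lv.voxel_volume_um3
        kept = segmentation.filter_small(lv, min_size_um3=5 * voxvol)
        assert kept.n_labels == 1
        assert kept.volumes_um3()[0] == pytest.approx(9 * voxvol)


class TestRegionGrow:
    def test_grows_within_tolerance_from_seed(self):
        data = np.full((5, 5, 5), 200, dtype=np.uint8)
        data[2, 1:4, 1:4] = 80
        grid = VoxelGrid(data=data, spacing_nm=SPACING)
        out = segmentation.region_grow(grid, seeds_vox=[(2, 2, 2)], tolerance=10.0)
        assert out.sum() == 9
        assert out[2, 2, 2]


class TestFullChain:
    def test_metaphase_phantom_default_params(self, metaphase_segmented, metaphase_phantom):
        labels, t = metaphase_segmented
        grid, truth = metaphase_phantom
        # threshold falls between the shell gray (120) and background (200)
        assert 120.0 < t < 200.0
        assert labels.n_labels == truth.labels.n_labels == 46
        # total segmented volume exceeds chromatin truth: the mask includes
        # the dark periphery shell around each chromosome
        assert labels.volumes_um3().sum() > truth.volume_um3.sum()
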