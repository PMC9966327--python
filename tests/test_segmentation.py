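"""Adaptive thresholding, components, and gradient-guided splitting."""

import numpy as np
import pytest
from scipy import ndimage

from fracmap.core import VolumeImage
from fracmap.segmentation import (
    SeedMarkers,
    adaptive_threshold,
    gradient_magnitude,
    label_components,
    split_fragment,
)


class TestAdaptiveThreshold:
    def test_constant_volume_empty(self):
        v = VolumeImage(np.full((20, 20, 20), 300.0))
        assert not adaptive_threshold(v, 3, 50).any()

    def test_noise_free_phantom_exact(self, intact_case):
        volume, truth = intact_case
        mask = adaptive_threshold(volume, window_radius=8, min_contrast=100)
        assert np.array_equal(mask, truth.intact_mask)

    def test_beats_best_global_threshold_on_ramped_volume(self):
        """Bright bar fading 700→300 against a background fading the
        opposite way 400→0: locally the bar always exceeds the
        background, but globally the bar's dim end (300) is darker than
        the background's bright end (400), so every global threshold
        misclassifies somewhere while the local rule separates them."""
        n = 60
        x = np.linspace(0, 1, n)[:, None, None]
        vol = np.broadcast_to(400.0 * (1 - x), (n, n, n)).copy()
        shell = np.zeros((n, n, n), bool)
        shell[:, 25:32, 25:32] = True  # a bar running along the ramp
        bar_vals = 700.0 - 400.0 * np.linspace(0, 1, n)
        vol[shell] = np.repeat(bar_vals, 49)  # C-order: 49 bar voxels per slice
        volume = VolumeImage(vol)
        # min_contrast above the background ramp's local range (~90 per
        # 13-voxel window) but below the bar/background contrast (~300)
        mask = adaptive_threshold(volume, window_radius=6, min_contrast=150)
        dice_adaptive = 2 * (mask & shell).sum() / (mask.sum() + shell.sum())

        best_global = 0.0
        for t in np.unique(np.round(vol, 0)):
            g = vol >= t
            denom = g.sum() + shell.sum()
            if denom:
                best_global = max(best_global, 2 * (g & shell).sum() / denom)
        assert dice_adaptive >= 0.95
        assert best_global < 0.95

    def test_window_larger_than_volume_rejected(self):
        v = VolumeImage(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError):
            adaptive_threshold(v, window_radius=6)


class TestGradientMagnitude:
    def test_constant_zero(self):
        v = VolumeImage(np.full((8, 8, 8), 5.0))
        assert np.allclose(gradient_magnitude(v), 0)

    @pytest.mark.parametrize("spacing, expected", [(1.0, 2.0), (0.5, 4.0)])
    def test_linear_ramp_interior(self, spacing, expected):
        idx = np.arange(10, dtype=float)
        v = VolumeImage(np.broadcast_to(2 * idx[:, None, None], (10, 10, 10)).copy(),
                        spacing=(spacing, 1, 1))
        g = gradient_magnitude(v)
        assert np.allclose(g[1:-1], expected)


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:4, 1:4, 1:4] = True
        m[7:11, 7:11, 7:11] = True
        labels = label_components(m, 26)
        assert labels.max() == 2
        # larger cube gets label 1
        assert (labels == 1).sum() == 64

    def test_edge_sharing_connectivity(self):
        """Two cubes meeting along one edge: connected at 26, separate
        at 6.  Oracle: brute-force flood fill on the toy grid."""
        m = np.zeros((6, 6, 6), bool)
        m[0:2, 0:2, 0:2] = True
        m[2:4, 2:4, 0:2] = True  # shares the edge at (2,2,z)

        def flood_count(mask, conn):
            lab, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, conn))
            return n

        assert label_components(m, 26).max() == flood_count(m, 3) == 1
        assert label_components(m, 6).max() == flood_count(m, 1) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5, 5), bool), 26).max() == 0

    def test_min_voxels_filter(self):
        m = np.zeros((10, 10, 10), bool)
        m[1:5, 1:5, 1:5] = True
        m[8, 8, 8] = True
        labels = label_components(m, 26, min_voxels=27)
        assert labels.max() == 1
        assert labels[8, 8, 8] == 0


class TestSplitFragment:
    def test_bar_hand_example(self):
        """1x1x7 bar [10,10,10,2,10,10,10], markers at the ends: the
        stated loop removes exactly index 2... the highest-gradient voxel
        adjacent to the dip, splitting {0,1} from {3..6}.

        Hand execution: central-difference gradients are
        [0,0,4,0,4,0,0]; ties broken toward the smaller index, so voxel
        (0,0,2) is removed first and the bar disconnects.
        """
        vals = np.array([10, 10, 10, 2, 10, 10, 10], dtype=float).reshape(1, 1, 7)
        volume = VolumeImage(vals)
        mask = np.ones((1, 1, 7), bool)
        markers = SeedMarkers([(1, (0, 0, 0)), (2, (0, 0, 6))])
        labels, removed = split_fragment(volume, mask, markers, connectivity=6)
        assert list(np.argwhere(removed)[:, 2]) == [2]
        assert np.array_equal(labels.labels[0, 0], [1, 1, 0, 2, 2, 2, 2])

    def test_already_separate_components(self):
        vals = np.zeros((1, 1, 5))
        mask = np.array([[[True, True, False, True, True]]])
        markers = SeedMarkers([(1, (0, 0, 0)), (2, (0, 0, 4))])
        labels, removed = split_fragment(VolumeImage(vals), mask, markers, 6)
        assert not removed.any()
        assert np.array_equal(labels.labels[0, 0], [1, 1, 0, 2, 2])

    def test_marker_outside_mask_rejected(self):
        vals = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[0] = True
        with pytest.raises(ValueError):
            split_fragment(VolumeImage(vals), mask,
                           SeedMarkers([(1, (0, 0, 0)), (2, (2, 2, 2))]), 26)

    def test_partition_disconnection_criticality(self, three_part_case):
        """On a real fractured phantom: labels + removed tile the mask,
        no two marker groups stay connected, and re-adding any removed
        voxel would rejoin two groups (checked by direct flood fill)."""
        from fracmap.studies import markers_from_truth
        from fracmap.segmentation import adaptive_threshold
        from fracmap._voxels import connectivity_structure

        volume, truth = three_part_case
        markers = markers_from_truth(truth)
        mask = adaptive_threshold(volume, 8, 100)
        labels, removed = split_fragment(volume, mask, markers, 26)

        assert np.array_equal((labels.labels > 0) | removed, mask)
        assert not (removed & (labels.labels > 0)).any()

        struct = connectivity_structure(26)
        kept = mask & ~removed
        lab, _ = ndimage.label(kept, structure=struct)
        comp_of_group = {g: lab[idx] for g, idx in markers.markers}
        assert len(set(comp_of_group.values())) == len(comp_of_group)

        # criticality oracle: a removed voxel must touch >= 2 components
        # holding different marker groups
        comp_groups: dict[int, set] = {}
        for g, idx in markers.markers:
            comp_groups.setdefault(int(lab[idx]), set()).add(g)
        offsets = np.argwhere(struct) - 1
        offsets = offsets[np.any(offsets != 0, axis=1)]
        for ijk in np.argwhere(removed):
            touched = set()
            for off in offsets:
                n = ijk + off
                if np.any(n < 0) or np.any(n >= np.array(kept.shape)):
                    continue
                c = int(lab[tuple(n)])
                if c:
                    touched |= comp_groups.get(c, set())
            assert len(touched) >= 2, f"removed voxel {ijk} is not critical"
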