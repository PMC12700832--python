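import numpy as np
import pytest

from nanoquant.quantify import (
    estimate_background,
    label_instances,
    measure_instances,
    summarize_organs,
)
from nanoquant.volume_io import LabelVolume, VoxelGrid


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent oracle: breadth-first flood fill, pure python."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    out = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if out[start]:
            continue
        next_label += 1
        queue = [start]
        out[start] = next_label
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                        and 0 <= nx < mask.shape[2]
                        and mask[nz, ny, nx] and not out[nz, ny, nx]):
                    out[nz, ny, nx] = next_label
                    queue.append((nz, ny, nx))
    return out


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same components up to label renaming."""
    if (a > 0).sum() != (b > 0).sum() or a.max() != b.max():
        return False
    pairs = set(zip(a[a > 0].tolist(), b[a > 0].tolist()))
    return len(pairs) == a.max() and len({p[1] for p in pairs}) == a.max()


class TestLabelInstances:
    def test_two_separated_cubes(self):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[0:2, 0:2, 0:2] = 1
        mask[5:7, 5:7, 5:7] = 1
        labels = label_instances(mask)
        assert labels.max() == 2

    def test_corner_touching_voxels_by_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[0, 0, 0] = 1
        mask[1, 1, 1] = 1  # shares only a corner
        assert label_instances(mask, connectivity=26).max() == 1
        assert label_instances(mask, connectivity=6).max() == 2

    def test_empty_mask(self):
        assert label_instances(np.zeros((4, 4, 4), dtype=np.uint8)).max() == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            label_instances(np.full((2, 2, 2), 3, dtype=np.uint8))

    def test_labels_in_scan_order(self):
        mask = np.zeros((1, 1, 9), dtype=np.uint8)
        mask[0, 0, [0, 4, 8]] = 1
        labels = label_instances(mask)
        assert labels[0, 0, 0] == 1 and labels[0, 0, 4] == 2 and labels[0, 0, 8] == 3

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_oracle_equivalence_on_random_masks(self, connectivity):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            shape = tuple(int(rng.integers(4, 33)) for _ in range(3))
            density = rng.uniform(0.05, 0.5)
            mask = (rng.random(shape) < density).astype(np.uint8)
            ours = label_instances(mask, connectivity)
            oracle = flood_fill_label(mask, connectivity)
            assert partitions_equal(ours, oracle)


class TestEstimateBackground:
    def test_direct_mean_excluding_mask(self):
        data = np.array([[[10.0, 10.0], [20.0, 20.0]]])
        labels = np.ones((1, 2, 2), dtype=np.int32)
        mask = np.zeros((1, 2, 2), dtype=np.uint8)
        mask[0, 1, :] = 1  # exclude the two 20s
        bt = estimate_background(VoxelGrid(data), LabelVolume(labels, {1: "liver"}), mask)
        assert bt[1] == pytest.approx(10.0)
        assert bt.segmented_voxels[1] == 2

    def test_empty_mask_gives_plain_mean(self):
        data = np.array([[[10.0, 30.0], [10.0, 30.0]]])
        labels = np.ones((1, 2, 2), dtype=np.int32)
        bt = estimate_background(
            VoxelGrid(data), LabelVolume(labels, {1: "liver"}), np.zeros((1, 2, 2), np.uint8)
        )
        assert bt[1] == pytest.approx(20.0)

    def test_fully_segmented_organ_errors(self):
        data = np.ones((1, 2, 2))
        labels = np.ones((1, 2, 2), dtype=np.int32)
        mask = np.ones((1, 2, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="entirely covered"):
            estimate_background(VoxelGrid(data), LabelVolume(labels, {1: "liver"}), mask)

    def test_fallback_uses_whole_volume_background(self):
        data = np.array([[[10.0, 10.0], [50.0, 50.0]]])
        labels = np.array([[[2, 2], [1, 1]]], dtype=np.int32)
        mask = np.array([[[0, 0], [1, 1]]], dtype=np.uint8)
        bt = estimate_background(
            VoxelGrid(data), LabelVolume(labels, {1: "liver", 2: "spleen"}),
            mask, allow_fallback=True,
        )
        assert bt[1] == pytest.approx(10.0)  # whole-volume unsegmented mean

    def test_bright_masked_voxels_never_change_background(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(10, 20, size=(4, 4, 4))
        labels = np.ones((4, 4, 4), dtype=np.int32)
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        organs = LabelVolume(labels, {1: "liver"})
        before = estimate_background(VoxelGrid(data), organs, mask)[1]
        bright = data.copy()
        bright[0, 0, 0] = 1e6
        mask[0, 0, 0] = 1
        after = estimate_background(VoxelGrid(bright), organs, mask)[1]
        # excluding the newly masked voxel, the mean moves only because the
        # voxel left the average, never because of its new brightness
        expected = (data.sum() - data[0, 0, 0]) / (data.size - 1)
        assert after == pytest.approx(expected)
        assert abs(after - before) < 1.0


class TestMeasureInstances:
    def _setup(self):
        data = np.full((2, 3, 3), 10.0)
        labels = np.ones((2, 3, 3), dtype=np.int32)
        organs = LabelVolume(labels, {1: "liver"})
        return data, organs

    def test_direct_contrast_formula(self):
        data, organs = self._setup()
        data[0, 0, 0] = 30.0
        data[0, 0, 1] = 20.0
        inst = np.zeros((2, 3, 3), dtype=np.int32)
        inst[0, 0, 0] = 1
        inst[0, 0, 1] = 1
        mask = (inst > 0).astype(np.uint8)
        bt = estimate_background(VoxelGrid(data), organs, mask)
        table = measure_instances(VoxelGrid(data), organs, inst, bt)
        assert len(table) == 1
        assert table.loc[0, "contrast"] == pytest.approx((30 - 10) / 10 + (20 - 10) / 10)
        assert table.loc[0, "voxel_count"] == 2
        assert table.loc[0, "sum_raw"] == pytest.approx(50.0)

    def test_instance_at_background_intensity_has_zero_contrast(self):
        data, organs = self._setup()
        inst = np.zeros((2, 3, 3), dtype=np.int32)
        inst[1, 1, 1] = 1
        bt = estimate_background(VoxelGrid(data), organs, (inst > 0).astype(np.uint8))
        table = measure_instances(VoxelGrid(data), organs, inst, bt)
        assert table.loc[0, "contrast"] == pytest.approx(0.0)

    def test_majority_organ_assignment(self):
        data = np.full((1, 2, 5), 10.0)
        labels = np.array([[[1, 1, 1, 2, 2], [1, 1, 1, 2, 2]]], dtype=np.int32)
        organs = LabelVolume(labels, {1: "liver", 2: "spleen"})
        inst = np.array([[[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]]], dtype=np.int32)
        data[0, 0, 2] = 100.0
        bt = estimate_background(VoxelGrid(data), organs, (inst > 0).astype(np.uint8))
        table = measure_instances(VoxelGrid(data), organs, inst, bt)
        assert table.loc[0, "organ_label"] == 1  # 3 of 5 voxels

    def test_centroid_and_bbox(self):
        data, organs = self._setup()
        inst = np.zeros((2, 3, 3), dtype=np.int32)
        inst[0, 0, 0] = 1
        inst[0, 2, 2] = 1
        bt = estimate_background(VoxelGrid(data), organs, (inst > 0).astype(np.uint8))
        table = measure_instances(VoxelGrid(data), organs, inst, bt)
        row = table.iloc[0]
        assert (row.centroid_z, row.centroid_y, row.centroid_x) == (0.0, 1.0, 1.0)
        assert (row.z_min, row.z_max) == (0, 1)
        assert (row.y_min, row.y_max) == (0, 3)
        assert bool(row.on_border)

    def test_min_voxel_filter(self):
        data, organs = self._setup()
        inst = np.zeros((2, 3, 3), dtype=np.int32)
        inst[0, 0, 0] = 1
        inst[1, 1:3, 1:3] = 2
        bt = estimate_background(VoxelGrid(data), organs, (inst > 0).astype(np.uint8))
        table = measure_instances(VoxelGrid(data), organs, inst, bt, min_voxels=2)
        assert list(table["instance_id"]) == [2]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(10, 20, (6, 6, 6))
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[1:5, 1:5, 1:5] = 1
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[2, 2, 2] = 1
        mask[2, 2, 3] = 1

        def run(d, l, m):
            organs = LabelVolume(l, {1: "liver"})
            from nanoquant.quantify import label_instances
            inst = label_instances(m)
            bt = estimate_background(VoxelGrid(d), organs, m)
            return measure_instances(VoxelGrid(d), organs, inst, bt), bt

        base, bt0 = run(data, labels, mask)
        shift = (1, 0, 1)
        d2 = np.roll(data, shift, axis=(0, 1, 2))
        l2 = np.roll(labels, shift, axis=(0, 1, 2))
        m2 = np.roll(mask, shift, axis=(0, 1, 2))
        moved, bt1 = run(d2, l2, m2)
        assert bt1[1] == pytest.approx(bt0[1])
        assert moved.loc[0, "contrast"] == pytest.approx(base.loc[0, "contrast"])
        assert moved.loc[0, "centroid_z"] == base.loc[0, "centroid_z"] + 1
        assert moved.loc[0, "centroid_x"] == base.loc[0, "centroid_x"] + 1


class TestSummaries:
    def test_no_instances_reports_zeros(self, toy_volume):
        grid, organs, _ = toy_volume
        empty_mask = np.zeros(grid.shape, dtype=np.uint8)
        bt = estimate_background(grid, organs, empty_mask)
        inst = np.zeros(grid.shape, dtype=np.int32)
        table = measure_instances(grid, organs, inst, bt)
        summaries = summarize_organs(table, organs, bt)
        assert len(summaries) == 2
        assert all(s.n_instances == 0 and s.total_contrast == 0.0 for s in summaries)

    def test_additivity(self, toy_volume):
        grid, organs, mask = toy_volume
        from nanoquant.quantify import label_instances
        inst = label_instances(mask)
        bt = estimate_background(grid, organs, mask)
        table = measure_instances(grid, organs, inst, bt)
        summaries = summarize_organs(table, organs, bt)
        assert sum(s.total_contrast for s in summaries) == pytest.approx(
            table["contrast"].sum(), abs=0
        )
        assert sum(s.total_voxels for s in summaries) == int(mask.sum())

    def test_conservation_on_phantom(self, small_phantom):
        from nanoquant.quantify import label_instances
        mask = (small_phantom.gt_instances > 0).astype(np.uint8)
        inst = label_instances(mask)
        bt = estimate_background(small_phantom.volume, small_phantom.organs, mask)
        table = measure_instances(small_phantom.volume, small_phantom.organs, inst, bt)
        summaries = summarize_organs(table, small_phantom.organs, bt)
        organ_total = sum(s.total_contrast for s in summaries)
        outside = table[table["organ_label"] == 0]["contrast"].sum()
        assert organ_total + outside == pytest.approx(table["contrast"].sum(), abs=1e-9)
        assert int(table["voxel_count"].sum()) == int(mask.sum())
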