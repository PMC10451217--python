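import logging

import numpy as np
import pytest

from onstrain.pointcloud import (
    ImageStack,
    Label,
    LabeledPointCloud,
    interpolate_slices,
    masks_to_points,
    read_cloud,
    voxelize,
    write_cloud,
)


def make_disk_slice(radius_vox: int, size: int = 15) -> np.ndarray:
    y, x = np.mgrid[:size, :size]
    c = size // 2
    return (np.hypot(x - c, y - c) <= radius_vox).astype(np.int16)


class TestMasksToPoints:
    def test_single_voxel(self):
        vol = np.zeros((1, 1, 1), dtype=int)
        vol[0, 0, 0] = 2
        cloud = masks_to_points(ImageStack(vol, [1, 1, 1]))
        assert len(cloud) == 1
        assert cloud.labels[0] == 2

    def test_full_grid_count_and_spacing(self):
        vol = np.full((3, 3, 3), int(Label.ON))
        stack = ImageStack(vol, [0.5, 0.5, 2.0])
        cloud = masks_to_points(stack)
        assert len(cloud) == 27
        xs = np.unique(cloud.points[:, 0])
        assert np.allclose(np.diff(xs), 0.5)

    def test_empty_volume_errors(self):
        with pytest.raises(ValueError):
            masks_to_points(ImageStack(np.zeros((2, 2, 2), int), [1, 1, 1]))

    def test_voxelized_sphere_centroid(self, rng):
        # symmetry: centroid of sphere-shell voxel centers stays at center
        n = 4000
        pts = rng.normal(size=(n, 3))
        pts = 12.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        center = np.array([3.0, -2.0, 7.0])
        cloud = LabeledPointCloud(pts + center, np.ones(n, int))
        stack = voxelize(cloud, [0.312, 0.312, 2.0])
        back = masks_to_points(stack)
        spacing = np.array([0.312, 0.312, 2.0])
        assert np.linalg.norm(back.points.mean(axis=0) - center) < 0.5 * spacing.max()


class TestVoxelize:
    def test_single_point_single_voxel(self):
        cloud = LabeledPointCloud([[0.0, 0.0, 0.0]], [3])
        stack = voxelize(cloud, [1, 1, 1])
        assert (stack.volume != 0).sum() == 1
        assert masks_to_points(stack).points[0] == pytest.approx([0, 0, 0])

    def test_sphere_voxel_count_matches_volume(self, rng):
        # solid ball sampled finely; occupied-voxel count ~ volume / voxel
        r = 12.0
        gx = np.arange(-r, r, 0.312)
        gz = np.arange(-r, r, 2.0)
        X, Y, Z = np.meshgrid(gx, gx, gz, indexing="ij")
        P = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
        P = P[np.linalg.norm(P, axis=1) <= r]
        cloud = LabeledPointCloud(P, np.ones(len(P), int))
        stack = voxelize(cloud, [0.312, 0.312, 2.0])
        count = int((stack.volume != 0).sum())
        expected = 4 / 3 * np.pi * r**3 / (0.312 * 0.312 * 2.0)
        assert abs(count - expected) / expected < 0.10

    def test_grid_aligned_roundtrip_identity(self, rng):
        pts = rng.integers(0, 10, size=(50, 3)).astype(float) * [0.5, 0.5, 2.0]
        pts = np.unique(pts, axis=0)
        cloud = LabeledPointCloud(pts, np.full(len(pts), 2))
        stack = voxelize(cloud, [0.5, 0.5, 2.0])
        back = masks_to_points(stack)
        a = set(map(tuple, np.round(cloud.points, 9)))
        b = set(map(tuple, np.round(back.points, 9)))
        assert a == b
        # voxelize(masks_to_points(stack)) reproduces the label volume
        stack2 = voxelize(back, [0.5, 0.5, 2.0], origin=stack.origin)
        assert np.array_equal(stack.volume, stack2.volume)


class TestInterpolateSlices:
    def test_identical_slices_reproduced(self):
        disk = make_disk_slice(4)
        vol = np.stack([disk, disk], axis=2)
        out = interpolate_slices(ImageStack(vol, [1, 1, 2.0]), 2)
        assert out.volume.shape[2] == 3
        assert np.array_equal(out.volume[:, :, 1], disk)
        assert out.spacing[2] == pytest.approx(1.0)

    def test_concentric_disks_interpolate_radius(self):
        vol = np.stack([make_disk_slice(3), make_disk_slice(5)], axis=2)
        out = interpolate_slices(ImageStack(vol, [1, 1, 2.0]), 2)
        mid = out.volume[:, :, 1]
        # signed-distance midpoint: radius-4 disk, within 1 voxel
        area = mid.sum()
        r_eff = np.sqrt(area / np.pi)
        assert abs(r_eff - 4.0) <= 1.0

    def test_label_vocabulary_and_inplane_spacing_preserved(self):
        vol = np.stack([make_disk_slice(3) * 2, make_disk_slice(5) * 2], axis=2)
        out = interpolate_slices(ImageStack(vol, [0.3, 0.3, 2.0]), 3)
        assert set(np.unique(out.volume)) <= {0, 2}
        assert out.spacing[0] == 0.3 and out.spacing[1] == 0.3

    def test_single_sided_label_leaves_gap(self, caplog):
        a = make_disk_slice(4)
        b = np.zeros_like(a)
        vol = np.stack([a, b], axis=2)
        with caplog.at_level(logging.WARNING, logger="onstrain.pointcloud"):
            out = interpolate_slices(ImageStack(vol, [1, 1, 2.0]), 2)
        assert out.volume[:, :, 1].sum() == 0
        assert any("one side" in r.message for r in caplog.records)

    def test_factor_below_two_rejected(self):
        vol = np.zeros((4, 4, 3), int)
        vol[1, 1, :] = 1
        with pytest.raises(ValueError):
            interpolate_slices(ImageStack(vol, [1, 1, 1]), 1)


class TestCloudIO:
    def _cloud(self):
        return LabeledPointCloud(
            [[0.123456789, -1, 2], [3, 4, 5], [-6, 7.5, 8]], [1, 2, 6], "coronal"
        )

    @pytest.mark.parametrize("ext", ["ply", "csv"])
    def test_roundtrip(self, tmp_path, ext):
        cloud = self._cloud()
        path = tmp_path / f"c.{ext}"
        write_cloud(cloud, path)
        back = read_cloud(path)
        assert np.allclose(back.points, cloud.points, atol=1e-6)
        assert np.array_equal(back.labels, cloud.labels)

    def test_csv_shuffled_columns_parsed_by_name(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("label,z,x,y\n2,3.0,1.0,2.0\n6,6.0,4.0,5.0\n")
        cloud = read_cloud(path)
        assert np.allclose(cloud.points, [[1, 2, 3], [4, 5, 6]])
        assert list(cloud.labels) == [2, 6]

    def test_ply_missing_label_property_errors(self, tmp_path):
        path = tmp_path / "c.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 1\n"
            "property double x\nproperty double y\nproperty double z\n"
            "end_header\n0 0 0\n"
        )
        with pytest.raises(ValueError, match="label"):
            read_cloud(path)

    def test_csv_missing_column_errors(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("x,y,z\n0,0,0\n")
        with pytest.raises(ValueError, match="label"):
            read_cloud(path)


def test_nifti_stack_roundtrip(tmp_path):
    from onstrain.pointcloud import read_stack, write_stack

    vol = np.zeros((5, 6, 7), dtype=np.int16)
    vol[2, 3, 4] = 2
    stack = ImageStack(vol, [0.312, 0.312, 2.0], origin=[1.0, -2.0, 3.0])
    path = tmp_path / "s.nii.gz"
    write_stack(stack, path)
    back = read_stack(path)
    assert np.array_equal(back.volume, vol)
    assert np.allclose(back.spacing, stack.spacing)
    assert np.allclose(back.origin, stack.origin)
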