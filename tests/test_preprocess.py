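import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thyrus.compounding import VoxelVolume
from thyrus.nn.losses import dice_score
from thyrus.preprocess import (
    apply_geometry,
    normalize_slices,
    reorient_axial,
    resize_center,
    restore_mask,
)

AXIAL_AXES = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # cols: z, y, x


@pytest.fixture()
def blob_volume():
    zz, yy, xx = np.mgrid[0:20, 0:72, 0:80]
    mask = (((yy - 40) / 16.0) ** 2 + ((xx - 36) / 13.0) ** 2 + ((zz - 10) / 8.0) ** 2) < 1
    img = 0.3 + 0.5 * mask.astype(np.float32)
    vol = VoxelVolume(img, np.zeros(3), [0.5, 0.4, 0.4], AXIAL_AXES)
    return vol, mask


class TestReorient:
    def test_axial_volume_unchanged_bitwise(self, blob_volume):
        vol, _ = blob_volume
        out = reorient_axial(vol)
        assert np.array_equal(out.values, vol.values)
        assert np.array_equal(out.axes, vol.axes)

    def test_pure_permutation_inverted_exactly(self, blob_volume):
        vol, _ = blob_volume
        permuted = VoxelVolume(np.transpose(vol.values, (2, 1, 0)), vol.origin,
                               vol.spacing[[2, 1, 0]], np.eye(3))
        out = reorient_axial(permuted)
        assert np.array_equal(out.values, vol.values)
        # world positions preserved
        idx = np.array([2, 5, 7])
        assert np.allclose(out.index_to_world(idx), permuted.index_to_world(idx[::-1]))

    def test_idempotent_including_resampling_path(self, blob_volume):
        vol, _ = blob_volume
        R = Rotation.from_euler("zx", [15, 8], degrees=True).as_matrix()
        rotated = VoxelVolume(vol.values, vol.origin, vol.spacing, R @ vol.axes)
        once = reorient_axial(rotated)
        twice = reorient_axial(once)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.axes, twice.axes)

    def test_degenerate_axes_rejected(self, blob_volume):
        vol, _ = blob_volume
        with pytest.raises(ValueError):
            VoxelVolume(vol.values, vol.origin, vol.spacing, np.zeros((3, 3)))


class TestResizeRestore:
    def test_slice_count_preserved(self, blob_volume):
        vol, _ = blob_volume
        stack = resize_center(vol, (64, 64))
        assert len(stack) == vol.values.shape[0]

    def test_centered_target_size_volume_unchanged(self):
        rng = np.random.default_rng(3)
        base = rng.random((5, 64, 64)).astype(np.float32)
        img = base + base[:, ::-1] + base[:, :, ::-1] + base[:, ::-1, ::-1]  # symmetric → centred
        vol = VoxelVolume(img, np.zeros(3), [0.5, 0.4, 0.4], AXIAL_AXES)
        stack = resize_center(vol, (64, 64))
        assert np.allclose(stack.slices, img, atol=1e-5)

    def test_mask_roundtrip_dice(self, blob_volume):
        """resize → restore keeps ≥0.98 Dice on a smooth mask."""
        vol, mask = blob_volume
        stack = resize_center(vol, (64, 64))
        mask_t = apply_geometry(mask.astype(np.float32), stack.geometry, order=0)
        restored = restore_mask(mask_t > 0.5, stack.geometry)
        assert dice_score(restored.values, mask) >= 0.98

    def test_roundtrip_changes_few_pixels(self, blob_volume):
        vol, mask = blob_volume
        stack = resize_center(vol, (64, 64))
        mask_t = apply_geometry(mask.astype(np.float32), stack.geometry, order=0)
        back = restore_mask(mask_t > 0.5, stack.geometry).values.astype(bool)
        twice = apply_geometry(back.astype(np.float32), stack.geometry, order=0)
        frac_changed = np.mean(twice != mask_t)
        assert frac_changed <= 0.01

    def test_empty_and_full_masks(self, blob_volume):
        vol, _ = blob_volume
        stack = resize_center(vol, (64, 64))
        n = len(stack)
        empty = restore_mask(np.zeros((n, 64, 64)), stack.geometry)
        assert empty.values.sum() == 0
        full = restore_mask(np.ones((n, 64, 64)), stack.geometry)
        g = stack.geometry
        rows = np.clip(np.arange(g.row0, g.row0 + g.window), 0, vol.values.shape[1] - 1)
        assert full.values.sum() > 0
        # nothing outside the crop window is set
        outside = np.ones_like(full.values, dtype=bool)
        r0, c0 = max(g.row0, 0), max(g.col0, 0)
        outside[:, r0 : g.row0 + g.window, c0 : g.col0 + g.window] = False
        assert full.values[outside].sum() == 0

    def test_slice_count_mismatch_rejected(self, blob_volume):
        vol, _ = blob_volume
        stack = resize_center(vol, (64, 64))
        with pytest.raises(ValueError):
            restore_mask(np.zeros((3, 64, 64)), stack.geometry)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            resize_center(VoxelVolume(np.zeros((0, 4, 4)), np.zeros(3), np.ones(3), AXIAL_AXES),
                          (32, 32))


def test_normalize_slices_zero_mean_unit_variance():
    rng = np.random.default_rng(0)
    s = rng.random((4, 16, 16)).astype(np.float32) * 7 + 3
    out = normalize_slices(s)
    assert np.allclose(out.mean(axis=(1, 2)), 0, atol=1e-5)
    assert np.allclose(out.std(axis=(1, 2)), 1, atol=1e-4)
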