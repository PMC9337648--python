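import numpy as np
import pytest

from thyrus.acquisition import TrackedFrame, TrackedSweep, mask_sweep
from thyrus.compounding import (
    CompoundingParams,
    VoxelVolume,
    compound,
    fill_holes,
    sweep_bounding_box,
)
from thyrus.geometry import RigidTransform
from thyrus.nn.losses import dice_score


def flat_sweep(value=1.0, n_frames=9, px=12, spacing=1.0, z_step=0.5, shift=(0.0, 0.0, 0.0)):
    frames = [
        TrackedFrame(
            np.full((px, px), value, dtype=np.float32),
            (spacing, spacing),
            RigidTransform(np.eye(3), np.asarray(shift) + [0.0, 0.0, i * z_step]),
            float(i),
        )
        for i in range(n_frames)
    ]
    return TrackedSweep(frames, "left", 2.0)


class TestBoundingBox:
    def test_single_frame_box_is_padded_frame_rectangle(self):
        sw = flat_sweep(n_frames=1, px=10, spacing=1.0)
        lo, hi = sweep_bounding_box(sw, pad=0.3)
        assert np.allclose(lo, [-0.3, -0.3, -0.3])
        assert np.allclose(hi, [9.3, 9.3, 0.3])

    def test_translation_equivariance(self):
        lo0, hi0 = sweep_bounding_box(flat_sweep())
        lo1, hi1 = sweep_bounding_box(flat_sweep(shift=(5.0, 0.0, 0.0)))
        assert np.allclose(lo1 - lo0, [5, 0, 0])
        assert np.allclose(hi1 - hi0, [5, 0, 0])

    def test_box_of_union_is_union_of_boxes(self):
        a = flat_sweep(n_frames=1)
        b = flat_sweep(n_frames=1, shift=(0, 0, 7.0))
        both = TrackedSweep(a.frames + [
            TrackedFrame(b.frames[0].pixels, b.frames[0].pixel_spacing, b.frames[0].pose, 1.0)
        ], "left", 2.0)
        lo, hi = sweep_bounding_box(both)
        lo_a, hi_a = sweep_bounding_box(a)
        lo_b, hi_b = sweep_bounding_box(b)
        assert np.allclose(lo, np.minimum(lo_a, lo_b))
        assert np.allclose(hi, np.maximum(hi_a, hi_b))

    def test_empty_sweep_raises(self):
        with pytest.raises(ValueError):
            sweep_bounding_box(TrackedSweep([], "left", 2.0))


class TestCompound:
    def test_constant_frames_give_constant_covered_voxels(self):
        sw = flat_sweep(value=3.25)
        vol, wt = compound(sw, CompoundingParams(voxel_spacing=0.5))
        covered = wt.values > 0
        assert covered.any()
        assert np.array_equal(np.unique(vol.values[covered]), [3.25])

    def test_gaussian_kernel_preserves_constants(self):
        sw = flat_sweep(value=2.5)
        vol, wt = compound(sw, CompoundingParams(voxel_spacing=0.5, kernel="gaussian"))
        assert np.abs(vol.values[wt.values > 0] - 2.5).max() < 1e-5

    def test_frame_order_invariance(self):
        sw = flat_sweep()
        rng = np.random.default_rng(0)
        for f in sw.frames:
            f.pixels[...] = rng.random(f.pixels.shape).astype(np.float32)
        perm_frames = [sw.frames[i] for i in rng.permutation(len(sw.frames))]
        # keep timestamps increasing for the container invariant
        perm_frames = [
            TrackedFrame(f.pixels, f.pixel_spacing, f.pose, float(i))
            for i, f in enumerate(perm_frames)
        ]
        sw2 = TrackedSweep(perm_frames, "left", 2.0)
        v1, w1 = compound(sw, CompoundingParams(voxel_spacing=0.5))
        v2, w2 = compound(sw2, CompoundingParams(voxel_spacing=0.5))
        assert np.allclose(v1.values, v2.values, atol=1e-6)
        assert np.array_equal(w1.values, w2.values)

    def test_intensities_stay_within_input_range(self, clean_sweep):
        vol, wt = compound(clean_sweep, CompoundingParams(voxel_spacing=0.5))
        lo = min(f.pixels.min() for f in clean_sweep.frames)
        hi = max(f.pixels.max() for f in clean_sweep.frames)
        cov = wt.values > 0
        assert vol.values[cov].min() >= lo - 1e-6
        assert vol.values[cov].max() <= hi + 1e-6

    def test_voxel_budget_cap(self):
        sw = flat_sweep()
        with pytest.raises(ValueError, match="coarser"):
            compound(sw, CompoundingParams(voxel_spacing=0.01, max_voxels=1000))

    def test_noiseless_mask_sweep_recovers_geometry(self, ellipsoid_phantom, clean_sweep):
        """Compounded + thresholded noiseless mask sweep vs analytic
        voxelization: Dice ≥ 0.95 at 0.3 mm."""
        ms = mask_sweep(clean_sweep)
        cp = CompoundingParams(voxel_spacing=0.3)
        vol, wt = compound(ms, cp)
        vol, wt = fill_holes(vol, wt, cp)
        pred = vol.values > 0.5
        shape = vol.values.shape
        ii = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
        analytic = ellipsoid_phantom.contains(vol.index_to_world(ii))
        assert dice_score(pred, analytic) >= 0.95


class TestFillHoles:
    def test_full_coverage_is_identity(self):
        vals = np.random.default_rng(1).random((6, 6, 6)).astype(np.float32)
        vol = VoxelVolume(vals, np.zeros(3), np.ones(3))
        wt = vol.with_values(np.ones_like(vals))
        out, _ = fill_holes(vol, wt, CompoundingParams())
        assert np.array_equal(out.values, vals)

    def test_single_interior_hole_filled_with_neighbourhood_value(self):
        vals = np.full((7, 7, 7), 2.0, dtype=np.float32)
        w = np.ones_like(vals)
        vals[3, 3, 3] = 0.0
        w[3, 3, 3] = 0.0
        vol = VoxelVolume(vals, np.zeros(3), np.ones(3))
        out, w2 = fill_holes(vol, vol.with_values(w), CompoundingParams(hole_fill_radius=1))
        assert out.values[3, 3, 3] == pytest.approx(2.0)
        assert w2.values[3, 3, 3] > 0

    def test_filled_fraction_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        vals = np.full((16, 16, 16), 1.0, dtype=np.float32)
        w = (rng.random((16, 16, 16)) > 0.35).astype(np.float32)
        vol = VoxelVolume(vals * w, np.zeros(3), np.ones(3))
        fracs = []
        for r in (1, 2, 3):
            _, w2 = fill_holes(vol, vol.with_values(w), CompoundingParams(hole_fill_radius=r))
            fracs.append((w2.values > 0).mean())
        assert fracs[0] <= fracs[1] <= fracs[2]
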