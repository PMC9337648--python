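"""Volume-to-network preprocessing: axial reorientation, in-plane resize
about the intensity centroid, and exact mask restoration to the source grid.

The network consumes fixed-size 2D axial slices; all geometric bookkeeping
(permutation/flips, crop window, scale) is stored in `SliceGeometry`, so a
per-slice mask predicted at network resolution maps back onto the source
voxel grid with a single nearest-neighbour resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .compounding import VoxelVolume

__all__ = ["SliceGeometry", "SliceStack", "reorient_axial", "resize_center", "restore_mask",
           "normalize_slices"]


@dataclass(frozen=True)
class SliceGeometry:
    """Invertible record of the in-plane crop/zoom applied to every slice."""

    source_shape: tuple[int, int, int]        # (slices, rows, cols)
    row0: int                                  # crop window origin (may be negative)
    col0: int
    window: int                                # square crop side, source pixels
    target_hw: tuple[int, int]
    source_origin: tuple[float, float, float]
    source_spacing: tuple[float, float, float]
    source_axes: tuple[float, ...]             # row-major 3×3

    def target_to_source(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map target pixel-centre indices to source pixel indices."""
        th, tw = self.target_hw
        r = self.row0 + (np.asarray(rows) + 0.5) * self.window / th - 0.5
        c = self.col0 + (np.asarray(cols) + 0.5) * self.window / tw - 0.5
        return r, c


@dataclass
class SliceStack:
    """Fixed-size axial slices plus the geometry to undo the resampling."""

    slices: np.ndarray          # (n_slices, H, W) float32
    geometry: SliceGeometry

    def __post_init__(self):
        if self.slices.ndim != 3:
            raise ValueError("slices must be (n, H, W)")
        if self.slices.shape[1:] != self.geometry.target_hw:
            raise ValueError("slice shape does not match geometry target")

    def __len__(self) -> int:
        return self.slices.shape[0]


def _axis_permutation(axes: np.ndarray) -> tuple[list[int], list[int], bool]:
    """Greedy assignment of volume axes to world axes (z, y, x order for the
    output: slicing axis first).  Returns (perm, signs, is_pure) where
    `is_pure` means the direction matrix is a signed permutation within tol."""
    want = [2, 1, 0]  # world z (superior–inferior) becomes index axis 0
    perm, signs = [], []
    used = set()
    for w in want:
        comps = [(abs(axes[w, i]), i) for i in range(3) if i not in used]
        comps.sort(reverse=True)
        _, i = comps[0]
        used.add(i)
        perm.append(i)
        signs.append(1 if axes[w, i] >= 0 else -1)
    # a signed permutation has exactly one ±1 per column, zeros elsewhere
    mags = np.sort(np.abs(axes), axis=0)
    is_pure = bool(np.allclose(mags[-1], 1.0, atol=1e-6) and np.allclose(mags[:2], 0.0, atol=1e-6))
    return perm, signs, is_pure


def reorient_axial(volume: VoxelVolume) -> VoxelVolume:
    """Rotate/permute the volume so index axis 0 runs superior–inferior
    (world z), axis 1 anterior–posterior (y), axis 2 lateral (x).

    A signed-permutation direction matrix is handled exactly (transpose and
    flips, values bit-equal); a general rotation is resampled once with
    linear interpolation onto a world-axis-aligned grid at the same spacing.
    Applying the function twice equals applying it once.
    """
    axes = volume.axes
    if abs(np.linalg.det(axes)) < 0.5:
        raise ValueError("degenerate axes")
    perm, signs, is_pure = _axis_permutation(axes)
    if is_pure:
        vals = np.transpose(volume.values, perm)
        new_axes = axes[:, perm] * np.array(signs)[None, :]
        origin = volume.origin.copy()
        spacing = volume.spacing[perm]
        for k, s in enumerate(signs):
            if s < 0:
                vals = np.flip(vals, axis=k)
                origin = origin + new_axes[:, k] * (-1) * spacing[k] * (vals.shape[k] - 1)
        # after flips new_axes columns point along +z, +y, +x
        return VoxelVolume(np.ascontiguousarray(vals), origin, spacing, new_axes)

    # general rotation: resample onto an axis-aligned grid (z, y, x index order)
    sp = float(volume.spacing.min())
    idx_corners = np.array(
        [[i, j, k] for i in (0, volume.values.shape[0] - 1)
         for j in (0, volume.values.shape[1] - 1)
         for k in (0, volume.values.shape[2] - 1)], dtype=float,
    )
    world = volume.index_to_world(idx_corners)
    lo, hi = world.min(axis=0), world.max(axis=0)
    n = np.floor((hi - lo) / sp).astype(int) + 1
    new_axes = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]).T  # cols: z,y,x
    origin = np.array([lo[0], lo[1], lo[2]])
    # output index (i,j,k) -> world (x=lo_x+k·sp, y=lo_y+j·sp, z=lo_z+i·sp)
    out_shape = (n[2], n[1], n[0])
    out = VoxelVolume(np.zeros(out_shape, dtype=volume.values.dtype), origin, np.full(3, sp), new_axes)
    ii = np.stack(np.meshgrid(*[np.arange(s) for s in out_shape], indexing="ij"), axis=-1)
    src_idx = volume.world_to_index(out.index_to_world(ii))
    vals = ndimage.map_coordinates(
        volume.values.astype(np.float32), np.moveaxis(src_idx, -1, 0), order=1, mode="constant"
    )
    return out.with_values(vals)


def resize_center(volume: VoxelVolume, target_hw: tuple[int, int] = (256, 256),
                  window: int | None = None) -> SliceStack:
    """Crop every axial slice about the volume's in-plane intensity centroid
    and scale to `target_hw`.

    One square window (side = min in-plane dimension unless given) is used
    for all slices so the stack shares a single invertible geometry.  The
    slice count is exactly the source slice count.
    """
    vals = np.asarray(volume.values, dtype=np.float32)
    if vals.size == 0 or vals.shape[0] == 0:
        raise ValueError("empty volume")
    th, tw = target_hw
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    if th != tw:
        raise ValueError("target must be square (slices are cropped square)")

    ns, h, w = vals.shape
    weight = vals - vals.min()
    tot = float(weight.sum())
    if tot <= 0:
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        rows = np.arange(h, dtype=np.float64)
        cols = np.arange(w, dtype=np.float64)
        cr = float((weight.sum(axis=(0, 2)) * rows).sum() / tot)
        cc = float((weight.sum(axis=(0, 1)) * cols).sum() / tot)
    win = int(window or min(h, w))
    row0 = int(round(cr - (win - 1) / 2.0))
    col0 = int(round(cc - (win - 1) / 2.0))

    geom = SliceGeometry(
        source_shape=(ns, h, w), row0=row0, col0=col0, window=win, target_hw=(th, tw),
        source_origin=tuple(volume.origin), source_spacing=tuple(volume.spacing),
        source_axes=tuple(volume.axes.reshape(-1)),
    )
    tr, tc = np.meshgrid(np.arange(th), np.arange(tw), indexing="ij")
    sr, sc = geom.target_to_source(tr, tc)
    out = np.empty((ns, th, tw), dtype=np.float32)
    coords = np.stack([sr, sc])
    for s in range(ns):
        out[s] = ndimage.map_coordinates(vals[s], coords, order=1, mode="constant")
    return SliceStack(out, geom)


def apply_geometry(values: np.ndarray, geometry: SliceGeometry, order: int = 0) -> np.ndarray:
    """Resample a source-grid stack (n, rows, cols) through an existing crop
    geometry (order=0 for masks, 1 for images); used to bring ground-truth
    masks to network resolution with exactly the image transform."""
    vals = np.asarray(values, dtype=np.float32)
    ns, h, w = geometry.source_shape
    if vals.shape != (ns, h, w):
        raise ValueError("values do not match geometry source shape")
    th, tw = geometry.target_hw
    tr, tc = np.meshgrid(np.arange(th), np.arange(tw), indexing="ij")
    coords = np.stack(geometry.target_to_source(tr, tc))
    out = np.empty((ns, th, tw), dtype=np.float32)
    for s in range(ns):
        out[s] = ndimage.map_coordinates(vals[s], coords, order=order, mode="constant")
    return out


def restore_mask(slice_masks: np.ndarray, geometry: SliceGeometry) -> VoxelVolume:
    """Map per-slice masks (n, H, W) back to the source voxel grid
    (nearest-neighbour, labels preserved)."""
    masks = np.asarray(slice_masks)
    ns, h, w = geometry.source_shape
    if masks.shape[0] != ns:
        raise ValueError(f"expected {ns} slice masks, got {masks.shape[0]}")
    if masks.shape[1:] != geometry.target_hw:
        raise ValueError("mask shape does not match geometry target")
    th, tw = geometry.target_hw
    # source pixel -> target pixel (inverse of target_to_source)
    sr, sc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    tr = (sr - geometry.row0 + 0.5) * th / geometry.window - 0.5
    tc = (sc - geometry.col0 + 0.5) * tw / geometry.window - 0.5
    ri = np.rint(tr).astype(int)
    ci = np.rint(tc).astype(int)
    ok = (ri >= 0) & (ri < th) & (ci >= 0) & (ci < tw)
    out = np.zeros((ns, h, w), dtype=np.uint8)
    rs, cs = sr[ok], sc[ok]
    rt, ct = ri[ok], ci[ok]
    for s in range(ns):
        out[s, rs, cs] = masks[s, rt, ct].astype(np.uint8)
    axes = np.asarray(geometry.source_axes).reshape(3, 3)
    return VoxelVolume(out, np.asarray(geometry.source_origin),
                       np.asarray(geometry.source_spacing), axes)


def normalize_slices(slices: np.ndarray) -> np.ndarray:
    """Per-slice zero-mean/unit-variance normalization (network input scale)."""
    s = np.asarray(slices, dtype=np.float32)
    mean = s.mean(axis=(-2, -1), keepdims=True)
    std = s.std(axis=(-2, -1), keepdims=True)
    return (s - mean) / np.maximum(std, 1e-6)
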