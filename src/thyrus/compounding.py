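"""3D compounding of tracked 2D sweeps by forward splatting.

Every frame pixel deposits its intensity into the voxel grid with kernel
weights (nearest voxel, or a Gaussian over the 3×3×3 neighbourhood); a
voxel's value is the weight-normalized mean of its deposits.  Forward
splatting handles irregular freehand frame spacing without an explicit
interpolation model; the weight volume doubles as a coverage map, and
normalized averaging fills interior gaps afterwards.

The volume's axes follow the mean frame orientation, so a straight sweep
yields an approximately axis-aligned anatomy regardless of probe attitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["VoxelVolume", "CompoundingParams", "sweep_bounding_box", "compound", "fill_holes"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid in world millimetres.

    index (i,j,k) ↦ world  origin + axes @ (spacing · (i,j,k)); voxel-centre
    convention, 0-based indices, `axes` columns are the world directions of
    the three index axes.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be positive")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")

    @property
    def affine(self) -> np.ndarray:
        """4×4 index→world affine (NIfTI convention)."""
        A = np.eye(4)
        A[:3, :3] = self.axes * self.spacing[None, :]
        A[:3, 3] = self.origin
        return A

    @classmethod
    def from_affine(cls, values: np.ndarray, affine: np.ndarray) -> "VoxelVolume":
        M = np.asarray(affine, dtype=float)
        spacing = np.linalg.norm(M[:3, :3], axis=0)
        axes = M[:3, :3] / spacing[None, :]
        return cls(values, M[:3, 3], spacing, axes)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * self.spacing @ self.axes.T + self.origin

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) @ self.axes / self.spacing

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "VoxelVolume":
        return VoxelVolume(values, self.origin.copy(), self.spacing.copy(), self.axes.copy())


@dataclass(frozen=True)
class CompoundingParams:
    """`gaussian_sigma` may be a scalar (isotropic) or a per-axis triple in
    the volume frame (in-plane x, in-plane y, sweep normal); an anisotropic
    kernel elongated along the sweep direction averages many frames'
    independent tracking errors without blurring in-plane."""

    voxel_spacing: float = 0.3          # mm, isotropic
    kernel: str = "nearest"             # nearest | gaussian
    gaussian_sigma: float | tuple[float, float, float] = 0.3   # mm
    hole_fill_radius: int = 2           # voxels
    max_voxels: int = 80_000_000

    def __post_init__(self):
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.kernel not in ("nearest", "gaussian"):
            raise ValueError("kernel must be 'nearest' or 'gaussian'")
        if self.kernel == "gaussian" and np.max(self.sigma_vector()) <= 0:
            raise ValueError("gaussian_sigma must be positive when kernel='gaussian'")

    def sigma_vector(self) -> np.ndarray:
        """Per-axis sigma; a zero entry means nearest-voxel along that axis."""
        s = np.asarray(self.gaussian_sigma, dtype=float)
        if (s < 0).any():
            raise ValueError("gaussian_sigma must be >= 0")
        return np.broadcast_to(s, (3,)).copy()


def _frame_corners(frame) -> np.ndarray:
    h, w = frame.pixels.shape
    sv, su = frame.pixel_spacing
    pts = np.array(
        [[0, 0, 0], [(w - 1) * su, 0, 0], [0, (h - 1) * sv, 0], [(w - 1) * su, (h - 1) * sv, 0]]
    )
    return frame.pose.apply(pts)


def sweep_bounding_box(sweep, pad: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """World-space AABB containing every frame corner, padded by `pad` mm."""
    if len(sweep.frames) == 0:
        raise ValueError("empty sweep")
    corners = np.concatenate([_frame_corners(f) for f in sweep.frames])
    return corners.min(axis=0) - pad, corners.max(axis=0) + pad


def _mean_orientation(sweep) -> np.ndarray:
    """Orthonormalized mean frame rotation (right-handed)."""
    M = np.mean([f.pose.rotation for f in sweep.frames], axis=0)
    u, _, vt = np.linalg.svd(M)
    R = u @ vt
    if np.linalg.det(R) < 0:
        u[:, -1] *= -1
        R = u @ vt
    return R


def compound(sweep, params: CompoundingParams | None = None
             ) -> tuple[VoxelVolume, VoxelVolume]:
    """Reconstruct a voxel volume from a tracked sweep by forward splatting.

    Returns (volume, weights).  Voxels never touched by any pixel have
    weight 0 and value 0; `fill_holes` interpolates interior gaps.
    """
    params = params or CompoundingParams()
    if len(sweep.frames) == 0:
        raise ValueError("empty sweep")
    sp = params.voxel_spacing
    R = _mean_orientation(sweep)

    # bounding box in the volume frame (axes = R columns)
    corners = np.concatenate([_frame_corners(f) for f in sweep.frames]) @ R
    lo = corners.min(axis=0) - sp
    hi = corners.max(axis=0) + sp
    shape = np.maximum(np.ceil((hi - lo) / sp).astype(int) + 1, 1)
    if int(np.prod(shape)) > params.max_voxels:
        raise ValueError(
            f"voxel budget exceeded ({np.prod(shape):,} > {params.max_voxels:,}); "
            "use a coarser voxel_spacing"
        )
    origin = R @ lo
    vol = VoxelVolume(np.zeros(shape, dtype=np.float32), origin, np.full(3, sp), R)

    nvox = int(np.prod(shape))
    wsum = np.zeros(nvox, dtype=np.float64)
    vsum = np.zeros(nvox, dtype=np.float64)

    # buffer splats across frames so bincount passes over the full grid are rare
    buf_flat: list[np.ndarray] = []
    buf_w: list[np.ndarray] = []
    buf_wv: list[np.ndarray] = []
    buf_n = 0

    def flush() -> None:
        nonlocal buf_n, wsum, vsum
        if not buf_flat:
            return
        flat = np.concatenate(buf_flat)
        wsum += np.bincount(flat, weights=np.concatenate(buf_w), minlength=nvox)
        vsum += np.bincount(flat, weights=np.concatenate(buf_wv), minlength=nvox)
        buf_flat.clear(); buf_w.clear(); buf_wv.clear()
        buf_n = 0

    def deposit(flat: np.ndarray, w: np.ndarray, wv: np.ndarray) -> None:
        nonlocal buf_n
        buf_flat.append(flat); buf_w.append(w); buf_wv.append(wv)
        buf_n += flat.size
        if buf_n >= 5_000_000:
            flush()

    # process frames in groups to keep peak memory bounded
    px_per_frame = int(np.prod(sweep.frames[0].pixels.shape))
    group = max(1, int(3_000_000 / px_per_frame))
    for g0 in range(0, len(sweep.frames), group):
        frames = sweep.frames[g0 : g0 + group]
        pts = np.concatenate([f.pixel_points_world().reshape(-1, 3) for f in frames])
        vals = np.concatenate([f.pixels.reshape(-1) for f in frames]).astype(np.float64)
        idx_f = (pts @ R - lo) / sp
        idx = np.rint(idx_f).astype(np.int64)
        np.clip(idx, 0, shape - 1, out=idx)
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        deposit(flat, np.ones(flat.size), vals)
    flush()
    wsum = wsum.reshape(shape)
    vsum = vsum.reshape(shape)

    if params.kernel == "gaussian":
        # separable smoothing of the deposit sums ≡ splatting every pixel
        # with a voxel-quantized Gaussian kernel (the normalized ratio is the
        # same kernel-weighted mean); a zero sigma keeps that axis nearest
        for axis, s_vox in enumerate(params.sigma_vector() / sp):
            if s_vox > 0:
                wsum = ndimage.gaussian_filter1d(wsum, s_vox, axis=axis,
                                                 mode="constant", truncate=2.5)
                vsum = ndimage.gaussian_filter1d(vsum, s_vox, axis=axis,
                                                 mode="constant", truncate=2.5)
        # clip filter underflow so emptiness stays well defined
        tiny = wsum.max() * 1e-9 if wsum.size else 0.0
        wsum[wsum <= tiny] = 0.0

    covered = wsum > 0
    out = np.zeros(shape, dtype=np.float32)
    out[covered] = (vsum[covered] / wsum[covered]).astype(np.float32)
    return vol.with_values(out), vol.with_values(wsum.astype(np.float32))


def fill_holes(volume: VoxelVolume, weights: VoxelVolume,
               params: CompoundingParams | None = None
               ) -> tuple[VoxelVolume, VoxelVolume]:
    """Fill interior gaps by normalized averaging within `hole_fill_radius`.

    A gap is an uncovered voxel inside the morphological closing of the
    coverage; voxels outside coverage stay empty.  Returns the filled volume
    and an updated coverage map (filled voxels get weight 1).
    """
    params = params or CompoundingParams()
    r = params.hole_fill_radius
    covered = np.asarray(weights.values) > 0
    if r <= 0 or covered.all() or not covered.any():
        return volume, weights
    struct = ndimage.generate_binary_structure(3, 3)
    # pad so the closing behaves as in an unbounded domain (the default
    # zero border would erode an r-wide band and shrink the hull)
    padded = np.pad(covered, r)
    hull = ndimage.binary_closing(padded, struct, iterations=r)[(slice(r, -r),) * 3]
    holes = hull & ~covered
    if not holes.any():
        return volume, weights
    size = 2 * r + 1
    num = ndimage.uniform_filter(volume.values * covered, size=size, mode="constant")
    den = ndimage.uniform_filter(covered.astype(np.float32), size=size, mode="constant")
    filled = volume.values.copy()
    ok = holes & (den > 0)
    filled[ok] = (num[ok] / den[ok]).astype(volume.values.dtype)
    new_w = weights.values.copy()
    new_w[ok] = np.maximum(new_w[ok], 1.0)
    return volume.with_values(filled), weights.with_values(new_w)
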