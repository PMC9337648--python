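"""Thyroid volume estimation: 2D ellipsoid formula and 3D voxel counting.

Clinical convention: caliper extents are centimetres, so the ellipsoid
formula 0.48·width·depth·length yields millilitres directly; voxel volumes
are mm³ and are converted to millilitres here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ELLIPSOID_CORRECTION = 0.48
MM3_PER_ML = 1000.0

__all__ = [
    "CaliperMeasurement",
    "VolumeEstimate",
    "ellipsoid_volume",
    "voxel_count_volume",
    "total_volume",
]


@dataclass(frozen=True)
class CaliperMeasurement:
    """Width, depth, length of one lobe in centimetres."""

    width: float
    depth: float
    length: float
    side: str = "left"

    def __post_init__(self):
        if min(self.width, self.depth, self.length) <= 0:
            raise ValueError("caliper extents must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class VolumeEstimate:
    """A volume in ml with its method and provenance."""

    volume: float
    method: str                    # ellipsoid2d | voxel3d | reference
    side: str = "total"            # left | right | total
    observer: str | None = None
    repeat: int | None = None

    def __post_init__(self):
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.method not in ("ellipsoid2d", "voxel3d", "reference"):
            raise ValueError(f"unknown method {self.method!r}")


def ellipsoid_volume(caliper: CaliperMeasurement, observer: str | None = None,
                     repeat: int | None = None) -> VolumeEstimate:
    """Ellipsoid-formula lobe volume: 0.48 × width × depth × length (cm → ml).

    The clinical correction factor 0.48 replaces the exact ellipsoid factor
    π/6 ≈ 0.524 to account for the non-ellipsoidal lobe shape; no isthmus
    term is added.
    """
    vol = ELLIPSOID_CORRECTION * caliper.width * caliper.depth * caliper.length
    return VolumeEstimate(vol, "ellipsoid2d", caliper.side, observer, repeat)


def voxel_count_volume(mask_volume, observer: str | None = None,
                       repeat: int | None = None, side: str | None = None) -> VolumeEstimate:
    """Volume of a binary mask: foreground-voxel count × voxel volume (→ ml)."""
    spacing = getattr(mask_volume, "spacing", None)
    if spacing is None:
        raise ValueError("mask volume must carry spacing metadata")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or (spacing <= 0).any():
        raise ValueError("spacing must be three positive lengths (mm)")
    count = int(np.asarray(mask_volume.values).astype(bool).sum())
    vol_ml = count * float(np.prod(spacing)) / MM3_PER_ML
    return VolumeEstimate(vol_ml, "voxel3d", side or "total", observer, repeat)


def total_volume(left: VolumeEstimate, right: VolumeEstimate) -> VolumeEstimate:
    """Total thyroid volume as the plain sum of the two lobe estimates."""
    if left.method != right.method:
        raise ValueError(f"method mismatch: {left.method} vs {right.method}")
    if left.observer != right.observer or left.repeat != right.repeat:
        raise ValueError("cannot sum estimates from different observations")
    return VolumeEstimate(
        left.volume + right.volume, left.method, "total", left.observer, left.repeat
    )
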