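"""File formats: NIfTI volumes, pose CSVs, YAML run configuration, manifests.

Volumes are written as NIfTI-2 (float64 affine fields, so the index→world
affine round-trips to machine precision; NIfTI-1 stores it in float32).
Sweeps serialize as a NIfTI frame stack plus a pose CSV with columns
frame_index, t, tx, ty, tz, qx, qy, qz, qw (mm, seconds, unit quaternions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .compounding import CompoundingParams, VoxelVolume
from .geometry import RigidTransform

POSE_COLUMNS = ["frame_index", "t", "tx", "ty", "tz", "qx", "qy", "qz", "qw"]

__all__ = [
    "read_volume",
    "write_volume",
    "write_sweep",
    "read_sweep",
    "RunConfig",
    "load_config",
    "write_manifest",
]


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a VoxelVolume as NIfTI-2 with its exact affine."""
    path = Path(path)
    img = nib.Nifti2Image(np.asarray(volume.values), volume.affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI file into a VoxelVolume (values and affine preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    return VoxelVolume.from_affine(values, affine)


def write_sweep(sweep, stem: str | Path) -> tuple[Path, Path]:
    """Serialize a sweep as `<stem>.nii` (frame stack; frame index is the
    third axis) + `<stem>_poses.csv` (recorded tracker poses)."""
    stem = Path(stem)
    frames = np.stack([f.pixels for f in sweep.frames], axis=-1)
    sv, su = sweep.pixel_spacing
    affine = np.diag([su, sv, 1.0, 1.0])  # in-plane mm; frame axis is unitless index
    nib.save(nib.Nifti2Image(frames, affine), str(stem.with_suffix(".nii")))
    rows = []
    for i, f in enumerate(sweep.frames):
        q = f.pose.quaternion()
        t = f.pose.translation
        rows.append([i, f.timestamp, t[0], t[1], t[2], q[0], q[1], q[2], q[3]])
    df = pd.DataFrame(rows, columns=POSE_COLUMNS)
    pose_path = Path(f"{stem}_poses.csv")
    df.to_csv(pose_path, index=False, float_format="%.9g")
    return stem.with_suffix(".nii"), pose_path


def read_sweep(stem: str | Path, frame_rate: float = 89.0, side: str = "left"):
    """Inverse of `write_sweep` (recorded poses only; simulation ground truth
    is not part of the on-disk format)."""
    from .acquisition import TrackedFrame, TrackedSweep

    stem = Path(stem)
    img = nib.load(str(stem.with_suffix(".nii")))
    frames_px = np.asanyarray(img.dataobj)
    su, sv = float(img.affine[0, 0]), float(img.affine[1, 1])
    poses = pd.read_csv(f"{stem}_poses.csv")
    missing = set(POSE_COLUMNS) - set(poses.columns)
    if missing:
        raise ValueError(f"pose CSV lacks columns: {sorted(missing)}")
    frames = []
    for _, row in poses.iterrows():
        pose = RigidTransform.from_quaternion(
            [row.qx, row.qy, row.qz, row.qw], [row.tx, row.ty, row.tz]
        )
        i = int(row.frame_index)
        frames.append(TrackedFrame(frames_px[..., i], (sv, su), pose, float(row.t)))
    return TrackedSweep(frames, side, frame_rate)


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end study run."""

    seed: int = 0
    output_dir: str = "results/study"
    n_volunteers: int = 8
    n_repeats: int = 3
    # acquisition (desk scale by default)
    image_px: int = 96
    pixel_mm: float = 0.35
    frame_rate: float = 89.0
    # compounding
    voxel_mm: float = 0.4
    kernel: str = "gaussian"
    sweep_smooth_sigma_mm: float = 1.4   # kernel sigma along the sweep direction
    hole_fill_radius: int = 2
    # preprocessing / network
    target_hw: int = 64
    crop_mm: float = 28.0
    n_enc_dec: int = 4
    base_channels: int = 16
    dropout: float = 0.5
    lr: float = 5e-4
    batch_size: int = 4
    max_epochs: int = 20
    slices_per_lobe: int = 16
    train_fraction: float = 0.7
    segmenter: str = "network"        # network | otsu (fast classical baseline)

    def validate(self) -> "RunConfig":
        if self.n_volunteers < 1 or self.n_repeats < 1:
            raise ValueError("n_volunteers and n_repeats must be >= 1")
        if self.target_hw % (2 ** self.n_enc_dec) != 0:
            raise ValueError("target_hw must be divisible by 2^n_enc_dec")
        if self.segmenter not in ("network", "otsu"):
            raise ValueError("segmenter must be 'network' or 'otsu'")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        CompoundingParams(voxel_spacing=self.voxel_mm, kernel=self.kernel,
                          gaussian_sigma=(0.0, 0.0, self.sweep_smooth_sigma_mm),
                          hole_fill_radius=self.hole_fill_radius)
        if min(self.image_px, self.pixel_mm, self.frame_rate, self.lr) <= 0:
            raise ValueError("acquisition/training scalars must be positive")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    valid = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()


def write_manifest(output_dir: str | Path, config: RunConfig, files: list[Path]) -> Path:
    """Record config and content hashes of the run's artifacts."""
    out = Path(output_dir) / "manifest.json"
    entries = {}
    for f in sorted(files, key=str):
        f = Path(f)
        entries[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    from . import __version__

    payload = {"thyrus_version": __version__, "config": asdict(config), "files": entries}
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
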