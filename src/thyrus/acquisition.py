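"""Simulated freehand tracked 2D ultrasound of lobe phantoms.

A sweep is a linear pass of the probe along the neck (superior–inferior)
with a small smooth hand wobble; each frame is a planar resampling of the
phantom's appearance model.  Appearance uses constant tissue-class means —
hypoechoic lobe interior, a brighter capsule rim, midlevel background with
smooth texture — under mild depth attenuation and multiplicative
Rayleigh-like speckle.  The tracker records each frame's pose with additive
zero-mean Gaussian error whose RMS matches the electromagnetic tracker
specification (1.40 mm position, 0.50° orientation); ground-truth per-frame
masks come from the *true* geometry, so tracking error propagates into the
compounded volumes exactly as it would in a real acquisition.

World frame: x lateral (left negative), y depth (anterior→posterior),
z superior–inferior.  Image columns map to x, rows to depth y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform, rotation_from_rotvec_deg
from .phantom import LobePhantom
from .rng import split_rng
from .volumetry import CaliperMeasurement

__all__ = [
    "AcquisitionParams",
    "ObserverProfile",
    "TrackedFrame",
    "TrackedSweep",
    "default_observers",
    "simulate_sweep",
    "simulate_caliper",
]

TRACKER_POSITION_RMS_MM = 1.40
TRACKER_ANGLE_RMS_DEG = 0.50


@dataclass(frozen=True)
class ObserverProfile:
    """A simulated physician: caliper habits and sweep handling.

    `caliper_bias` multiplies the true extent per axis (width, depth,
    length); `caliper_sd` is the relative SD of the lognormal measurement
    noise per axis.  Observer 3's 1.10 bias emulates the least experienced
    reader's systematic overestimation.
    """

    name: str = "MD1"
    caliper_bias: tuple[float, float, float] = (1.0, 1.0, 1.0)
    caliper_sd: tuple[float, float, float] = (0.05, 0.05, 0.05)
    sweep_speed: float = 10.0        # mm/s
    pose_noise_scale: float = 1.0

    def __post_init__(self):
        if any(s < 0 for s in self.caliper_sd):
            raise ValueError("caliper_sd must be >= 0")
        if self.sweep_speed <= 0:
            raise ValueError("sweep_speed must be > 0")


def default_observers() -> tuple[ObserverProfile, ...]:
    """Three observers with experience-graded bias/noise (most → least)."""
    return (
        ObserverProfile("MD1", (1.00, 1.00, 1.00), (0.05, 0.05, 0.05), 10.0, 1.0),
        ObserverProfile("MD2", (0.98, 0.98, 0.98), (0.06, 0.06, 0.06), 12.0, 1.0),
        ObserverProfile("MD3", (1.10, 1.10, 1.10), (0.08, 0.08, 0.08), 14.0, 1.0),
    )


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner/tracker settings.  Defaults reproduce the study hardware:
    89 fps video, 668×599 px frames at 0.0753×0.0751 mm, tracker RMS error
    1.40 mm / 0.50°.  `desk()` gives a coarsened configuration for CPU-scale
    experiments (same physics, fewer pixels and frames)."""

    frame_rate: float = 89.0
    image_shape: tuple[int, int] = (599, 668)          # (rows, cols)
    pixel_spacing: tuple[float, float] = (0.0751, 0.0753)  # (row, col) mm
    position_rms_mm: float = TRACKER_POSITION_RMS_MM
    angle_rms_deg: float = TRACKER_ANGLE_RMS_DEG
    speckle: bool = True
    rim_thickness_mm: float = 0.6
    wobble_deg: float = 1.5
    wobble_mm: float = 0.8
    attenuation_per_mm: float = 0.01
    sweep_margin_mm: float = 4.0
    probe_offset_mm: tuple[float, float] = (0.0, 0.0)   # (lateral, depth) mis-placement
    background_level: float = 0.45
    lobe_level: float = 0.25
    rim_level: float = 0.85
    texture_amp: float = 0.25

    def __post_init__(self):
        if self.frame_rate <= 0 or min(self.pixel_spacing) <= 0:
            raise ValueError("frame_rate and pixel_spacing must be positive")

    @classmethod
    def desk(cls, image_px: int = 96, pixel_mm: float = 0.35, frame_rate: float = 89.0,
             **overrides) -> "AcquisitionParams":
        return cls(
            frame_rate=frame_rate,
            image_shape=(image_px, image_px),
            pixel_spacing=(pixel_mm, pixel_mm),
            **overrides,
        )


@dataclass(frozen=True)
class TrackedFrame:
    """One grayscale frame with its recorded (tracker) pose."""

    pixels: np.ndarray                     # (rows, cols) float32
    pixel_spacing: tuple[float, float]     # (row, col) mm
    pose: RigidTransform                   # image plane (mm) -> world (mm)
    timestamp: float                       # s

    def __post_init__(self):
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")

    def pixel_points_world(self) -> np.ndarray:
        """World coordinates (rows, cols, 3) of every pixel centre."""
        h, w = self.pixels.shape
        sv, su = self.pixel_spacing
        v, u = np.meshgrid(np.arange(h) * sv, np.arange(w) * su, indexing="ij")
        pts = np.stack([u, v, np.zeros_like(u)], axis=-1)
        return self.pose.apply(pts)


@dataclass
class TrackedSweep:
    """Ordered tracked frames of one lobe sweep.

    `true_poses` (and `masks`, the analytic plane–phantom intersections)
    are simulation ground truth that a real acquisition would not have.
    """

    frames: list[TrackedFrame]
    side: str
    frame_rate: float
    true_poses: list[RigidTransform] = field(default_factory=list)
    masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.frames:
            ts = [f.timestamp for f in self.frames]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("timestamps must be strictly increasing")
            sp = self.frames[0].pixel_spacing
            if any(f.pixel_spacing != sp for f in self.frames):
                raise ValueError("all frames must share pixel_spacing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.frames[0].pixel_spacing

    def position_noise(self) -> np.ndarray:
        """Recorded-minus-true translations, (n, 3) mm."""
        return np.array(
            [f.pose.translation - p.translation for f, p in zip(self.frames, self.true_poses)]
        )

    def angle_noise_deg(self) -> np.ndarray:
        """Rotation angle of recorded·trueᵀ per frame, degrees."""
        out = []
        for f, p in zip(self.frames, self.true_poses):
            d = f.pose.rotation @ p.rotation.T
            cosang = np.clip((np.trace(d) - 1.0) / 2.0, -1.0, 1.0)
            out.append(np.degrees(np.arccos(cosang)))
        return np.array(out)


def _smooth_wobble(rng: np.random.Generator, t: np.ndarray, amplitude: float, n_modes: int = 3
                   ) -> np.ndarray:
    """Slow pseudo-random hand wobble: a few random-phase sinusoids, (len(t), 3)."""
    out = np.zeros((t.size, 3))
    if amplitude == 0 or t.size == 0:
        return out
    span = max(t[-1] - t[0], 1e-6)
    for _ in range(n_modes):
        freq = rng.uniform(0.3, 1.2) / span
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.3, 1.0, size=3) * amplitude / n_modes
        out += amp * np.sin(2 * np.pi * freq * t[:, None] + phase)
    return out


def simulate_sweep(
    phantom: LobePhantom,
    observer: ObserverProfile,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    companions: tuple[LobePhantom, ...] = (),
) -> TrackedSweep:
    """Simulate one tracked sweep over a lobe phantom.

    The probe translates superior→inferior at the observer's sweep speed,
    covering the phantom's z-extent plus a margin.  Recorded poses carry
    zero-mean Gaussian tracker noise with total RMS `position_rms_mm ·
    pose_noise_scale` (mm) and `angle_rms_deg · pose_noise_scale` (degrees);
    per-axis SD is RMS/√3 so the 3-D error norm has the specified RMS.

    `companions` are additional tissue structures (an isthmus bridge)
    rendered into the images but excluded from the ground-truth masks.
    """
    params = params or AcquisitionParams()
    rng_path = split_rng(seed, "sweep-path")
    rng_noise = split_rng(seed, "sweep-noise")
    rng_tex = split_rng(seed, "sweep-texture")

    h, w = params.image_shape
    sv, su = params.pixel_spacing

    # world z-range of the phantom from its transformed bounding box
    lo, hi = phantom.local_bounds()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    zc = phantom.pose.apply(corners)[:, 2]
    z0, z1 = zc.min() - params.sweep_margin_mm, zc.max() + params.sweep_margin_mm
    step = observer.sweep_speed / params.frame_rate
    n_frames = int(np.ceil((z1 - z0) / step)) + 1
    t = np.arange(n_frames) / params.frame_rate

    center = phantom.pose.translation
    ox, oy = params.probe_offset_mm
    base_t = np.array(
        [center[0] + ox - (w - 1) / 2 * su, center[1] + oy - (h - 1) / 2 * sv, z0]
    )
    wob_t = _smooth_wobble(rng_path, t, params.wobble_mm)
    wob_r = _smooth_wobble(rng_path, t, params.wobble_deg)

    sd_pos = params.position_rms_mm * observer.pose_noise_scale / np.sqrt(3.0)
    sd_ang = params.angle_rms_deg * observer.pose_noise_scale / np.sqrt(3.0)
    noise_t = rng_noise.normal(0.0, sd_pos, size=(n_frames, 3)) if sd_pos > 0 else np.zeros((n_frames, 3))
    noise_r = rng_noise.normal(0.0, sd_ang, size=(n_frames, 3)) if sd_ang > 0 else np.zeros((n_frames, 3))

    # in-plane pixel offsets, reused across frames
    v, u = np.meshgrid(np.arange(h) * sv, np.arange(w) * su, indexing="ij")
    plane = np.stack([u, v, np.zeros_like(u)], axis=-1)
    depth_gain = np.exp(-params.attenuation_per_mm * v).astype(np.float32)

    inner = LobePhantom(
        tuple(max(s - params.rim_thickness_mm, 1e-3) for s in phantom.semi_axes),
        phantom.bend, phantom.bumps, phantom.exponent, phantom.pose, phantom.side,
    )

    frames, true_poses, masks = [], [], []
    hit = False
    for i in range(n_frames):
        rot = rotation_from_rotvec_deg(wob_r[i])
        trans = base_t + wob_t[i] + np.array([0.0, 0.0, observer.sweep_speed * t[i]])
        true = RigidTransform(rot, trans)
        pts = true.apply(plane)
        inside = phantom.contains(pts)
        rim = inside & ~inner.contains(pts)
        hit = hit or bool(inside.any())

        img = np.full((h, w), params.background_level, dtype=np.float32)
        if params.texture_amp > 0:
            tex = ndimage.gaussian_filter(rng_tex.standard_normal((h, w)), 3.0)
            tex /= max(tex.std(), 1e-6)
            img *= 1.0 + params.texture_amp * tex.astype(np.float32) * 0.5
        img[inside] = params.lobe_level
        for comp in companions:  # e.g. an isthmus bridge: imaged, never in the mask
            img[comp.contains(pts)] = params.lobe_level
        img[rim] = params.rim_level
        img *= depth_gain
        if params.speckle:
            speck = rng_tex.rayleigh(scale=np.sqrt(2 / np.pi), size=(h, w)).astype(np.float32)
            img *= ndimage.gaussian_filter(speck, 0.7)
        recorded = RigidTransform(rotation_from_rotvec_deg(noise_r[i]) @ rot, trans + noise_t[i])
        frames.append(TrackedFrame(img, (sv, su), recorded, float(t[i])))
        true_poses.append(true)
        masks.append(inside)

    if not hit:
        raise ValueError("sweep path never intersects the phantom")
    return TrackedSweep(frames, phantom.side, params.frame_rate, true_poses, masks)


def mask_sweep(sweep: TrackedSweep) -> TrackedSweep:
    """A copy of the sweep whose pixel data are the ground-truth masks
    (used for geometric oracle checks of the compounding)."""
    frames = [
        TrackedFrame(m.astype(np.float32), f.pixel_spacing, f.pose, f.timestamp)
        for f, m in zip(sweep.frames, sweep.masks)
    ]
    return TrackedSweep(frames, sweep.side, sweep.frame_rate, sweep.true_poses, sweep.masks)


def simulate_caliper(
    phantom: LobePhantom,
    observer: ObserverProfile,
    seed: int = 0,
) -> CaliperMeasurement:
    """One observer's caliper read of a lobe: true principal-axis extents,
    scaled by the observer's per-axis bias, with lognormal relative noise.

    Returns width/depth/length in centimetres, as read off a 2D scan.
    """
    extents_mm = np.asarray(_cached_extents(phantom))
    rng = split_rng(seed, "caliper")
    bias = np.asarray(observer.caliper_bias, dtype=float)
    sd = np.asarray(observer.caliper_sd, dtype=float)
    # lognormal with unit median and relative SD ≈ sd
    sigma = np.sqrt(np.log1p(sd**2))
    noise = np.exp(rng.normal(0.0, 1.0, size=3) * sigma)
    vals_cm = extents_mm / 10.0 * bias * noise
    return CaliperMeasurement(
        width=float(vals_cm[0]), depth=float(vals_cm[1]), length=float(vals_cm[2]),
        side=phantom.side,
    )


_EXTENTS_CACHE: dict[int, tuple[tuple[float, float, float], object]] = {}


def _cached_extents(phantom: LobePhantom) -> tuple[float, float, float]:
    key = id(phantom)
    hit = _EXTENTS_CACHE.get(key)
    if hit is not None and hit[1] is phantom:
        return hit[0]
    ext = phantom.principal_extents()
    _EXTENTS_CACHE[key] = (ext, phantom)
    if len(_EXTENTS_CACHE) > 256:
        _EXTENTS_CACHE.pop(next(iter(_EXTENTS_CACHE)))
    return ext
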