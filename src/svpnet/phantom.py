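"""Synthetic fundus phantoms: disc images with ground-truth masks and
disc-centered videos with a vein whose caliber either pulses at a
cardiac-like frequency (label "present") or stays constant ("absent").

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs. Geometry is 0-based (row, col); the mask covers the
disc ellipse only — vessels are rendered in the frame but never annotated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError, GeometryError

PRESENT = "present"
ABSENT = "absent"

# amplitude of the smooth background texture, relative to intensity range
_TEXTURE_AMPLITUDE = 0.03


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic image or clip."""

    image_height: int = 128
    image_width: int = 128
    disc_center: tuple[float, float] = (64.0, 64.0)   # (row, col)
    disc_radii: tuple[float, float] = (22.0, 26.0)    # (vertical, horizontal)
    disc_intensity: float = 0.85
    background_intensity: float = 0.45
    vessel_base_width: float = 5.0
    vessel_intensity: float = 0.15
    pulsation_amplitude: float = 0.3    # fraction of base width, in [0, 1)
    pulsation_frequency: float = 1.2    # Hz, cardiac-like
    frame_rate: float = 30.0
    duration: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self, *, for_video: bool = False) -> None:
        if not (0.0 <= self.pulsation_amplitude < 1.0):
            raise ContractError("pulsation_amplitude must be in [0, 1)")
        for name in ("disc_intensity", "background_intensity", "vessel_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be non-negative")
        if self.vessel_base_width <= 0:
            raise ContractError("vessel_base_width must be positive")
        r0, c0 = self.disc_center
        rv, rh = self.disc_radii
        if rv <= 0 or rh <= 0:
            raise GeometryError("disc radii must be positive")
        if (r0 - rv < 0 or r0 + rv > self.image_height - 1
                or c0 - rh < 0 or c0 + rh > self.image_width - 1):
            raise GeometryError(
                f"disc (center {self.disc_center}, radii {self.disc_radii}) "
                f"is not interior to a {self.image_height}x{self.image_width} frame")
        if for_video and self.n_frames < 30:
            raise ContractError(
                f"frame_rate*duration gives {self.n_frames} frames; "
                "the classifier contract requires at least 30")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("disc_center", "disc_radii"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VideoClip:
    """Ordered stack of grayscale frames (T, H, W) in [0,1] with a frame rate."""

    frames: np.ndarray
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class LabeledImage:
    frame: np.ndarray          # (H, W) in [0, 1]
    mask: np.ndarray           # (H, W) in {0, 1}, uint8
    spec: PhantomSpec | None = None


@dataclass
class LabeledClip:
    clip: VideoClip
    label: str                 # "present" | "absent"
    spec: PhantomSpec = field(default_factory=PhantomSpec)


def ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    """Binary disc mask: (row-r0)^2/rv^2 + (col-c0)^2/rh^2 <= 1."""
    r0, c0 = spec.disc_center
    rv, rh = spec.disc_radii
    rows = np.arange(spec.image_height)[:, None]
    cols = np.arange(spec.image_width)[None, :]
    inside = ((rows - r0) ** 2 / rv ** 2 + (cols - c0) ** 2 / rh ** 2) <= 1.0
    return inside.astype(np.uint8)


def _background_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth, zero-mean low-frequency field (blurred white noise)."""
    raw = rng.normal(size=(spec.image_height, spec.image_width))
    smooth = gaussian_filter(raw, sigma=8.0)
    peak = np.abs(smooth).max()
    if peak == 0:
        return smooth
    return smooth * (_TEXTURE_AMPLITUDE / peak)


def _bezier_points(p0, p1, p2, n: int = 400) -> np.ndarray:
    """Dense samples of a quadratic Bezier curve through control points."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _curve_coverage(shape: tuple[int, int], points: np.ndarray,
                    width: float) -> np.ndarray:
    """Anti-aliased coverage of a polyline of the given width.

    coverage = clip(width/2 + 0.5 - distance, 0, 1), so summing coverage
    across a perpendicular cross-section recovers the width to ~1 px.
    """
    h, w = shape
    rows = np.arange(h, dtype=float)[:, None, None]
    cols = np.arange(w, dtype=float)[None, :, None]
    dr = rows - points[:, 0][None, None, :]
    dc = cols - points[:, 1][None, None, :]
    dist = np.sqrt(dr * dr + dc * dc).min(axis=2)
    return np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)


def _vertical_vein_coverage(spec: PhantomSpec, width: float) -> np.ndarray:
    """Coverage of a straight vertical vein through the disc center column."""
    col0 = spec.disc_center[1]
    dist = np.abs(np.arange(spec.image_width, dtype=float) - col0)
    profile = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    return np.broadcast_to(profile, (spec.image_height, spec.image_width)).copy()


def _random_vessel_coverage(spec: PhantomSpec, rng: np.random.Generator,
                            width: float) -> np.ndarray:
    """A curved vessel crossing the disc, entering and leaving at frame edges."""
    h, w = spec.image_height, spec.image_width
    r0, c0 = spec.disc_center
    angle = rng.uniform(0, np.pi)
    reach = float(np.hypot(h, w))
    d = np.array([np.cos(angle), np.sin(angle)])
    mid = np.array([r0, c0]) + rng.normal(0, min(spec.disc_radii) / 3.0, size=2)
    p0 = mid - reach * d
    p2 = mid + reach * d
    # bow the curve sideways for a vessel-like arc
    normal = np.array([-d[1], d[0]])
    p1 = mid + normal * rng.uniform(-0.15, 0.15) * reach
    points = _bezier_points(p0, p1, p2)
    keep = ((points[:, 0] >= -width) & (points[:, 0] <= h + width)
            & (points[:, 1] >= -width) & (points[:, 1] <= w + width))
    points = points[keep]
    if len(points) == 0:
        points = np.array([[r0, c0]])
    return _curve_coverage((h, w), points, width)


def _compose(spec: PhantomSpec, mask: np.ndarray, texture: np.ndarray,
             vessel_coverages: list[np.ndarray]) -> np.ndarray:
    """Disc over textured background, with vessels as additive darkening.

    Vessel rendering shifts the local base value toward vessel_intensity by
    (vessel - background) * coverage, so when vessel_intensity equals
    background_intensity the disc pixels keep disc_intensity exactly.
    """
    frame = np.where(mask.astype(bool), spec.disc_intensity,
                     spec.background_intensity + texture)
    delta = spec.vessel_intensity - spec.background_intensity
    for cov in vessel_coverages:
        frame = frame + delta * cov
    return np.clip(frame, 0.0, 1.0)


def make_disc_image(spec: PhantomSpec) -> LabeledImage:
    """One fundus-like frame: bright elliptical disc, 2-4 dark vessels, noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec)
    texture = _background_texture(spec, rng)
    n_vessels = int(rng.integers(2, 5))
    coverages = [_random_vessel_coverage(spec, rng, spec.vessel_base_width)
                 for _ in range(n_vessels)]
    frame = _compose(spec, mask, texture, coverages)
    if spec.noise_sd > 0:
        frame = np.clip(frame + rng.normal(0, spec.noise_sd, frame.shape), 0.0, 1.0)
    return LabeledImage(frame=frame, mask=mask, spec=spec)


def vein_width_at(spec: PhantomSpec, frame_index: int, label: str) -> float:
    """Analytic vein width w(t) = base * (1 + a*sin(2*pi*f*t/frame_rate))."""
    a = spec.pulsation_amplitude if label == PRESENT else 0.0
    t = frame_index / spec.frame_rate
    return spec.vessel_base_width * (1.0 + a * np.sin(
        2.0 * np.pi * spec.pulsation_frequency * t))


def make_svp_clip(spec: PhantomSpec, label: str) -> LabeledClip:
    """A clip whose single vein pulses (label present) or does not (absent)."""
    if label not in (PRESENT, ABSENT):
        raise ContractError(f"label must be {PRESENT!r} or {ABSENT!r}, got {label!r}")
    spec.validate(for_video=True)
    if label == PRESENT and spec.pulsation_amplitude <= 0:
        raise ContractError("label 'present' requires pulsation_amplitude > 0")
    if label == ABSENT:
        spec = spec.replace(pulsation_amplitude=0.0)
    rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec)
    texture = _background_texture(spec, rng)
    n = spec.n_frames
    frames = np.empty((n, spec.image_height, spec.image_width))
    for t in range(n):
        width = vein_width_at(spec, t, label)
        cov = _vertical_vein_coverage(spec, width)
        frame = _compose(spec, mask, texture, [cov])
        if spec.noise_sd > 0:
            frame = np.clip(frame + rng.normal(0, spec.noise_sd, frame.shape),
                            0.0, 1.0)
        frames[t] = frame
    return LabeledClip(clip=VideoClip(frames=frames, frame_rate=spec.frame_rate),
                       label=label, spec=spec)


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator,
                 seed: int, jitter_amplitude: bool) -> PhantomSpec:
    """Per-sample perturbation of center, radii and (optionally) amplitude."""
    h, w = base.image_height, base.image_width
    rv, rh = base.disc_radii
    rv = rv * rng.uniform(0.85, 1.15)
    rh = rh * rng.uniform(0.85, 1.15)
    max_shift = 0.08
    r0 = base.disc_center[0] + rng.uniform(-max_shift, max_shift) * h
    c0 = base.disc_center[1] + rng.uniform(-max_shift, max_shift) * w
    r0 = float(np.clip(r0, rv + 1, h - rv - 2))
    c0 = float(np.clip(c0, rh + 1, w - rh - 2))
    amp = base.pulsation_amplitude
    if jitter_amplitude and amp > 0:
        amp = float(np.clip(amp * rng.uniform(0.8, 1.2), 0.05, 0.95))
    return base.replace(disc_center=(r0, c0), disc_radii=(rv, rh),
                        pulsation_amplitude=amp, seed=seed)


def make_dataset(n_images: int, n_clips: int, base_spec: PhantomSpec | None = None,
                 seed: int = 0) -> tuple[list[LabeledImage], list[LabeledClip]]:
    """Label-balanced phantom dataset with per-sample jittered specs."""
    if n_clips % 2:
        raise ContractError("n_clips must be even for label balance")
    if base_spec is None:
        base_spec = PhantomSpec()
    base_spec.validate(for_video=n_clips > 0)
    rng = np.random.default_rng(seed)
    images = []
    for _ in range(n_images):
        child = int(rng.integers(0, 2 ** 31))
        images.append(make_disc_image(_jitter_spec(base_spec, rng, child, False)))
    clips = []
    for i in range(n_clips):
        label = PRESENT if i % 2 == 0 else ABSENT
        child = int(rng.integers(0, 2 ** 31))
        spec_i = _jitter_spec(base_spec, rng, child, label == PRESENT)
        clips.append(make_svp_clip(spec_i, label))
    return images, clips
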