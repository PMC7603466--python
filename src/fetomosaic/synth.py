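"""Synthetic fetoscopy-like data with exact ground truth.

Real fetoscopic video has no ground-truth inter-frame geometry, so this
module provides the controlled stand-in used for development and
evaluation:

* placenta-like *textures* — smooth low-contrast background crossed by
  dark curvilinear vessel-like structures, optionally with bright
  specular blobs;
* *patch pairs* with exact 4-point ground truth, minted either by the
  controlled rigid model (rotation + translation only, reflecting the
  remote-center-of-motion constraint of a fetoscope) or by independent
  random corner perturbation (the unconstrained regime used by generic
  deep-homography training);
* full *frame sequences* following circular / spiral / exploratory
  trajectories over a texture, with exact pairwise homographies and
  optional imaging artifacts (specular highlights, blur, occlusions,
  circular scope mask).

Geometry is exact by construction: ground truth comes from the corner
algebra, never from estimation, and only the pixel resampling is
approximate (bilinear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .homography import (
    FourPointHomography,
    apply_homography,
    default_corners,
    fourpt_to_matrix,
    normalize_homography,
    rigid_matrix,
    translation_matrix,
)

__all__ = [
    "PatchPair",
    "TrajectorySpec",
    "ArtifactConfig",
    "FrameSequence",
    "PlacementError",
    "TrajectoryError",
    "generate_texture",
    "generate_controlled_pair",
    "generate_perturbed_pair",
    "generate_sequence",
    "sample_patch",
    "DEFAULT_BETA_RANGE_DEG",
    "DEFAULT_D_RANGE_PX",
]

#: Controlled-generation parameter ranges at the 256x256 working
#: resolution: rotation beta in (-5, +5) degrees, translation d_x, d_y
#: in (-16, 16) pixels.
DEFAULT_BETA_RANGE_DEG: Tuple[float, float] = (-5.0, 5.0)
DEFAULT_D_RANGE_PX: Tuple[float, float] = (-16.0, 16.0)


class PlacementError(RuntimeError):
    """No valid patch placement found within the retry budget."""


class TrajectoryError(RuntimeError):
    """The trajectory footprint leaves the texture."""


@dataclass(frozen=True)
class PatchPair:
    """Two co-registered patches plus their exact 4-point ground truth.

    ``gt.corners`` are patch_a's corner coordinates in the source-image
    frame; ``gt`` maps patch_a corner positions onto the locations that
    patch_b was sampled from.
    """

    patch_a: np.ndarray
    patch_b: np.ndarray
    gt: FourPointHomography
    source_id: str = ""


@dataclass(frozen=True)
class TrajectorySpec:
    """Camera trajectory for a simulated sequence.

    Parameters
    ----------
    kind : {"circular", "spiral", "exploratory"}
    n_frames : int, >= 2
    step_px : float
        Per-frame translation magnitude (pixels).  For circular/spiral
        motion this sets the orbit arc length per frame (unless
        ``orbit_radius`` is given); for exploratory motion it bounds the
        per-axis random step.
    step_deg : float
        Per-frame rotation bound (degrees) for exploratory motion.
        Circular motion rotates with the orbit angle when ``rotate`` is
        true, so the loop closes exactly at the final frame.
    seed : int
    orbit_radius : float, optional
        Explicit orbit radius (circular) / final radius (spiral).
    rotate : bool
        Whether circular/spiral frames rotate with the orbit angle.
    turns : float
        Number of turns for the spiral.
    """

    kind: str
    n_frames: int
    step_px: float = 6.0
    step_deg: float = 2.0
    seed: int = 0
    orbit_radius: Optional[float] = None
    rotate: bool = True
    turns: float = 2.0

    def __post_init__(self):
        if self.kind not in ("circular", "spiral", "exploratory"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_frames": self.n_frames,
            "step_px": self.step_px,
            "step_deg": self.step_deg,
            "seed": self.seed,
            "orbit_radius": self.orbit_radius,
            "rotate": self.rotate,
            "turns": self.turns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectorySpec":
        return cls(**d)


@dataclass(frozen=True)
class ArtifactConfig:
    """Photometric artifact levels applied to rendered frames.

    Artifacts perturb intensities only; the geometric ground truth is
    untouched (as for a real scope, highlights move with the camera,
    not with the scene).
    """

    specular_level: float = 0.0
    blur_sigma: float = 0.0
    occlusion_prob: float = 0.0


@dataclass
class FrameSequence:
    """Ordered grayscale frames + optional mask and ground truth."""

    frames: list
    mask: Optional[Tuple[Tuple[float, float], float]] = None
    gt_pairwise: Optional[list] = None
    working_resolution: int = 256
    spec: Optional[TrajectorySpec] = None
    poses: Optional[list] = field(default=None, repr=False)

    def __post_init__(self):
        if self.gt_pairwise is not None and len(self.gt_pairwise) != len(self.frames) - 1:
            raise ValueError("gt_pairwise must have n_frames - 1 entries")


def generate_texture(
    width: int = 512,
    height: int = 512,
    vessel_density: float = 6.0,
    contrast: float = 0.35,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Generate a placenta-like grayscale texture in [0, 1].

    A smooth random background (large-scale illumination mottle plus a
    fine grain that gives local features something to lock onto) is
    darkened along random smooth curvilinear tracks of varying
    thickness, mimicking chorionic-plate vessels.

    Parameters
    ----------
    vessel_density : float
        Expected number of vessel tracks per 256x256 tile.
    contrast : float
        Overall amplitude of both background variation and vessel
        darkening; 0 gives a constant image.
    """
    if width <= 0 or height <= 0:
        raise ValueError("texture dimensions must be positive")
    rng = np.random.default_rng(rng)
    base = 0.55 * np.ones((height, width))
    if contrast > 0:
        smooth = gaussian_filter(rng.standard_normal((height, width)), sigma=24, mode="reflect")
        smooth /= max(np.abs(smooth).max(), 1e-12)
        grain = gaussian_filter(rng.standard_normal((height, width)), sigma=1.2, mode="reflect")
        grain /= max(np.abs(grain).max(), 1e-12)
        base = base + contrast * (0.45 * smooth + 0.25 * grain)

    n_vessels = int(round(vessel_density * (width * height) / 256.0**2))
    if n_vessels > 0 and contrast > 0:
        vessel_map = np.zeros((height, width))
        yy, xx = np.mgrid[0:height, 0:width]
        for _ in range(n_vessels):
            # random smooth track: a coarse random walk, densely interpolated
            n_ctrl = rng.integers(4, 8)
            pts = np.empty((n_ctrl, 2))
            pts[0] = rng.uniform([0, 0], [width, height])
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(30, 80)
            for i in range(1, n_ctrl):
                ang += rng.uniform(-0.8, 0.8)
                pts[i] = pts[i - 1] + step * np.array([np.cos(ang), np.sin(ang)])
            t = np.linspace(0, 1, n_ctrl)
            tt = np.linspace(0, 1, int(n_ctrl * step / 2))
            track_x = np.interp(tt, t, pts[:, 0])
            track_y = np.interp(tt, t, pts[:, 1])
            thickness = rng.uniform(1.5, 4.0)
            for cx, cy in zip(track_x, track_y):
                if -8 <= cx < width + 8 and -8 <= cy < height + 8:
                    x0, x1 = max(0, int(cx - 10)), min(width, int(cx + 11))
                    y0, y1 = max(0, int(cy - 10)), min(height, int(cy + 11))
                    d2 = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
                    stamp = np.exp(-d2 / (2 * thickness**2))
                    np.maximum(vessel_map[y0:y1, x0:x1], stamp, out=vessel_map[y0:y1, x0:x1])
        base = base - contrast * 0.9 * vessel_map
    return np.clip(base, 0.0, 1.0)


def sample_patch(
    image: np.ndarray,
    h: np.ndarray,
    origin: Tuple[float, float],
    patch_size: int,
) -> np.ndarray:
    """Resample ``image`` at ``h``-mapped patch-grid positions (bilinear).

    The patch grid covers frame coordinates ``origin + [0, patch_size)``;
    output pixel (p, q) is ``image`` evaluated at ``h @ (origin + (q, p))``.
    """
    ox, oy = origin
    xs = np.arange(patch_size, dtype=float) + ox
    ys = np.arange(patch_size, dtype=float) + oy
    gx, gy = np.meshgrid(xs, ys)
    h = np.asarray(h, dtype=float)
    denom = h[2, 0] * gx + h[2, 1] * gy + h[2, 2]
    mx = (h[0, 0] * gx + h[0, 1] * gy + h[0, 2]) / denom
    my = (h[1, 0] * gx + h[1, 1] * gy + h[1, 2]) / denom
    return map_coordinates(image, [my, mx], order=1, mode="constant", cval=0.0)


def _corners_inside(points: np.ndarray, width: int, height: int) -> bool:
    return bool(
        np.all(points[:, 0] >= 0)
        and np.all(points[:, 0] <= width - 1)
        and np.all(points[:, 1] >= 0)
        and np.all(points[:, 1] <= height - 1)
    )


def generate_controlled_pair(
    image: np.ndarray,
    beta_range_deg: Tuple[float, float] = DEFAULT_BETA_RANGE_DEG,
    d_range_px: Tuple[float, float] = DEFAULT_D_RANGE_PX,
    rng: Optional[np.random.Generator] = None,
    patch_size: int = 128,
    rotate_about_center: bool = False,
    max_retries: int = 100,
    source_id: str = "",
) -> PatchPair:
    """Mint a patch pair under the controlled rigid model.

    A patch ``P_A`` is sampled at a random location; the corners of
    ``P_B`` are the rigid map ``x' = R(beta) x + d`` of P_A's corners,
    with ``beta`` and ``d`` drawn uniformly from the configured ranges.
    By default the rotation is about the image coordinate origin (an
    option rotates about the patch center instead).  The ground truth
    is the exact corner algebra; ``patch_b`` is the source image
    resampled under the corresponding 3x3 matrix.
    """
    image = np.asarray(image, dtype=float)
    ih, iw = image.shape
    if ih < 2 * patch_size or iw < 2 * patch_size:
        raise ValueError(f"image must be at least {2 * patch_size} on each side")
    rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        beta = np.deg2rad(rng.uniform(*beta_range_deg))
        dx = rng.uniform(*d_range_px)
        dy = rng.uniform(*d_range_px)
        ox = int(rng.integers(0, iw - patch_size + 1))
        oy = int(rng.integers(0, ih - patch_size + 1))
        corners = default_corners(patch_size, patch_size) + [ox, oy]
        if rotate_about_center:
            cx, cy = corners.mean(axis=0)
            h = (
                translation_matrix(cx, cy)
                @ rigid_matrix(beta, dx, dy)
                @ translation_matrix(-cx, -cy)
            )
        else:
            h = rigid_matrix(beta, dx, dy)
        displaced = apply_homography(h, corners)
        if not _corners_inside(displaced, iw, ih):
            continue
        gt = FourPointHomography(corners=corners, displacements=displaced - corners)
        patch_a = image[oy : oy + patch_size, ox : ox + patch_size].copy()
        patch_b = sample_patch(image, h, (ox, oy), patch_size)
        return PatchPair(patch_a=patch_a, patch_b=patch_b, gt=gt, source_id=source_id)
    raise PlacementError(
        f"no valid placement after {max_retries} retries (transform too large for image)"
    )


def generate_perturbed_pair(
    image: np.ndarray,
    max_perturb: float = 32.0,
    rng: Optional[np.random.Generator] = None,
    patch_size: int = 128,
    integer: bool = True,
    max_retries: int = 100,
    source_id: str = "",
) -> PatchPair:
    """Mint a patch pair by independent random corner perturbation.

    Each of the four corners is displaced independently and uniformly
    by up to ``max_perturb`` pixels per axis (integer displacements by
    default), which yields a general projective ground truth — the
    unconstrained data model of generic deep homography training.
    """
    image = np.asarray(image, dtype=float)
    ih, iw = image.shape
    if ih < 2 * patch_size or iw < 2 * patch_size:
        raise ValueError(f"image must be at least {2 * patch_size} on each side")
    rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        if integer:
            disp = rng.integers(-int(max_perturb), int(max_perturb) + 1, size=(4, 2)).astype(float)
        else:
            disp = rng.uniform(-max_perturb, max_perturb, size=(4, 2))
        ox = int(rng.integers(0, iw - patch_size + 1))
        oy = int(rng.integers(0, ih - patch_size + 1))
        corners = default_corners(patch_size, patch_size) + [ox, oy]
        displaced = corners + disp
        if not _corners_inside(displaced, iw, ih):
            continue
        try:
            gt = FourPointHomography(corners=corners, displacements=disp)
            h = fourpt_to_matrix(gt)
        except ValueError:
            continue  # perturbation collapsed the quadrilateral
        patch_a = image[oy : oy + patch_size, ox : ox + patch_size].copy()
        patch_b = sample_patch(image, h, (ox, oy), patch_size)
        return PatchPair(patch_a=patch_a, patch_b=patch_b, gt=gt, source_id=source_id)
    raise PlacementError(
        f"no valid placement after {max_retries} retries (perturbation too large for image)"
    )


def _trajectory_poses(spec: TrajectorySpec, frame_size: int, texture_shape) -> list:
    """Frame-to-texture poses W_k (frame k content = texture at W_k x)."""
    th, tw = texture_shape
    fc = (frame_size - 1) / 2.0
    center = np.array([(tw - 1) / 2.0, (th - 1) / 2.0])
    to_center = translation_matrix(-fc, -fc)
    rng = np.random.default_rng(spec.seed)
    poses = []
    n = spec.n_frames
    if spec.kind in ("circular", "spiral"):
        if spec.kind == "circular":
            angles = 2.0 * np.pi * np.arange(n) / (n - 1)  # closes at the last frame
            radius = (
                spec.orbit_radius
                if spec.orbit_radius is not None
                else spec.step_px * (n - 1) / (2.0 * np.pi)
            )
            radii = np.full(n, radius)
        else:
            angles = 2.0 * np.pi * spec.turns * np.arange(n) / (n - 1)
            r_max = (
                spec.orbit_radius
                if spec.orbit_radius is not None
                else spec.step_px * (n - 1) / (2.0 * np.pi * spec.turns)
            )
            radii = r_max * np.arange(n) / (n - 1)
        for k in range(n):
            pos = center + radii[k] * np.array([np.cos(angles[k]), np.sin(angles[k])])
            rot = rigid_matrix(angles[k], 0.0, 0.0) if spec.rotate else np.eye(3)
            poses.append(translation_matrix(*pos) @ rot @ to_center)
    else:  # exploratory freehand random walk
        w = translation_matrix(*center) @ to_center
        poses.append(w)
        back = translation_matrix(fc, fc)
        fwd = translation_matrix(-fc, -fc)
        for _ in range(n - 1):
            dbeta = np.deg2rad(rng.uniform(-spec.step_deg, spec.step_deg))
            dx = rng.uniform(-spec.step_px, spec.step_px)
            dy = rng.uniform(-spec.step_px, spec.step_px)
            inc = back @ rigid_matrix(dbeta, dx, dy) @ fwd  # rigid about frame center
            w = w @ inc
            poses.append(w)
    return [normalize_homography(p) for p in poses]


def generate_sequence(
    texture: np.ndarray,
    spec: TrajectorySpec,
    frame_size: int = 256,
    mask_radius: Optional[float] = None,
    artifacts: Optional[ArtifactConfig] = None,
) -> FrameSequence:
    """Render a simulated fetoscopy sequence over a texture.

    Frame ``k`` is the texture resampled under the trajectory pose
    ``W_k``; the ground-truth pairwise homography mapping frame ``k+1``
    coordinates into frame ``k`` is ``W_k^{-1} W_{k+1}``, exact up to
    floating-point products.  Circular trajectories close their loop at
    the final frame by construction.  Photometric artifacts (specular
    blobs, blur, occlusion discs) never touch the ground truth.
    """
    texture = np.asarray(texture, dtype=float)
    artifacts = artifacts or ArtifactConfig()
    poses = _trajectory_poses(spec, frame_size, texture.shape)
    th, tw = texture.shape
    frame_corners = default_corners(frame_size, frame_size)
    for k, w in enumerate(poses):
        footprint = apply_homography(w, frame_corners)
        if not _corners_inside(footprint, tw, th):
            raise TrajectoryError(
                f"trajectory footprint leaves the texture at frame {k}; "
                "use a larger texture or a smaller orbit"
            )
    art_rng = np.random.default_rng(spec.seed + 1)
    frames = []
    for w in poses:
        frame = sample_patch(texture, w, (0.0, 0.0), frame_size)
        if artifacts.specular_level > 0:
            n_blobs = int(art_rng.poisson(3.0 * artifacts.specular_level))
            for _ in range(n_blobs):
                bx, by = art_rng.uniform(0, frame_size, size=2)
                rad = art_rng.uniform(2.0, 6.0)
                amp = art_rng.uniform(0.4, 0.9) * min(artifacts.specular_level, 1.0)
                y0, y1 = max(0, int(by - 3 * rad)), min(frame_size, int(by + 3 * rad) + 1)
                x0, x1 = max(0, int(bx - 3 * rad)), min(frame_size, int(bx + 3 * rad) + 1)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                frame[y0:y1, x0:x1] += amp * np.exp(
                    -((xx - bx) ** 2 + (yy - by) ** 2) / (2 * rad**2)
                )
        if artifacts.occlusion_prob > 0 and art_rng.uniform() < artifacts.occlusion_prob:
            bx, by = art_rng.uniform(0.2 * frame_size, 0.8 * frame_size, size=2)
            rad = art_rng.uniform(0.1, 0.25) * frame_size
            yy, xx = np.mgrid[0:frame_size, 0:frame_size]
            occ = (xx - bx) ** 2 + (yy - by) ** 2 < rad**2
            frame[occ] *= 0.15
        if artifacts.blur_sigma > 0:
            frame = gaussian_filter(frame, sigma=artifacts.blur_sigma, mode="nearest")
        frames.append(np.clip(frame, 0.0, 1.0))

    mask = None
    if mask_radius is not None:
        c = ((frame_size - 1) / 2.0, (frame_size - 1) / 2.0)
        yy, xx = np.mgrid[0:frame_size, 0:frame_size]
        inside = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= mask_radius**2
        frames = [np.where(inside, f, 0.0) for f in frames]
        mask = (c, float(mask_radius))

    gt_pairwise = [
        normalize_homography(np.linalg.inv(poses[k]) @ poses[k + 1])
        for k in range(len(poses) - 1)
    ]
    return FrameSequence(
        frames=frames,
        mask=mask,
        gt_pairwise=gt_pairwise,
        working_resolution=frame_size,
        spec=spec,
        poses=poses,
    )
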