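"""End-to-end mosaicking pipeline.

Raw fetoscope frames show a bright circular field of view on a dark
surround.  The pipeline detects that circular mask, crops the inscribed
square, normalizes frames to the grayscale working resolution, runs
median-consistent pairwise estimation along the sequence, accumulates
relative homographies into the mosaic plane, and renders the expanded
field-of-view mosaic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening
from skimage.transform import resize

from .consistent import ConsistencyConfig, PairEstimationFailure, consistent_estimate
from .estimators import Estimator
from .homography import (
    apply_homography,
    compose_relative,
    default_corners,
    normalize_homography,
    translation_matrix,
)
from .synth import FrameSequence

__all__ = [
    "CircularMask",
    "MaskDetectionError",
    "MosaicCanvas",
    "SequenceResult",
    "detect_circular_mask",
    "crop_inscribed_square",
    "preprocess_frame",
    "run_sequence",
    "render_mosaic",
]

logger = logging.getLogger("fetomosaic")

WORKING_RESOLUTION = 256  # grayscale side length frames are normalized to


class MaskDetectionError(RuntimeError):
    """No bright foreground found; the scope mask cannot be located."""


@dataclass(frozen=True)
class CircularMask:
    """Detected circular field of view: center (x, y) and radius, pixels."""

    center: Tuple[float, float]
    radius: float
    detected: bool = True  # False when the frame is full-field ("no mask")


@dataclass
class MosaicCanvas:
    """Rendered mosaic with per-pixel coverage bookkeeping."""

    image: np.ndarray
    coverage: np.ndarray
    origin_offset: Tuple[float, float]
    working_resolution: int


@dataclass
class SequenceResult:
    """Output of :func:`run_sequence`."""

    pairwise: List[np.ndarray]
    relative: List[np.ndarray]
    canvas: Optional[MosaicCanvas]
    failed_pairs: List[int] = field(default_factory=list)


def detect_circular_mask(frame: np.ndarray, min_radius: float = 8.0) -> CircularMask:
    """Locate the bright circular scope field on a dark surround.

    Otsu thresholding followed by morphological opening/closing isolates
    the foreground; the largest connected component's centroid and
    area-equivalent radius give the circle.  If the foreground covers
    more than 95% of the frame the content is full-field: "no mask" is
    reported and the inscribed full-frame circle returned.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=2)
    fh, fw = frame.shape
    full = CircularMask(
        center=((fw - 1) / 2.0, (fh - 1) / 2.0), radius=min(fw, fh) / 2.0, detected=False
    )
    if frame.max() - frame.min() < 1e-6:
        if frame.mean() > 0.25 * max(frame.max(), 1e-12) or frame.mean() > 0.1:
            return full  # uniformly bright: full-field content
        raise MaskDetectionError("frame is uniformly dark; no foreground component")
    thresh = threshold_otsu(frame)
    fg = frame > thresh
    selem = disk(3)
    fg = closing(opening(fg, selem), selem)
    if not fg.any():
        raise MaskDetectionError("no foreground component after thresholding")
    if fg.mean() > 0.95:
        return full
    lbl = label(fg)
    regions = regionprops(lbl)
    biggest = max(regions, key=lambda r: r.area)
    cy, cx = biggest.centroid
    radius = float(np.sqrt(biggest.area / np.pi))
    if radius < min_radius:
        raise MaskDetectionError(f"foreground too small (radius {radius:.1f} px)")
    return CircularMask(center=(float(cx), float(cy)), radius=radius, detected=True)


def crop_inscribed_square(
    frame: np.ndarray,
    center: Tuple[float, float],
    radius: float,
    margin: int = 0,
) -> np.ndarray:
    """Crop the axis-aligned square inscribed in the circular mask.

    The side is ``floor(radius * sqrt(2)) - 2 * margin`` (an optional
    safety margin mirrors the slightly conservative crops used on real
    scopes), centered on the circle center and clipped to the frame
    bounds with a warning if clipping occurs.
    """
    if radius < 16:
        raise ValueError(f"mask radius {radius:.1f} px too small to crop (< 16 px)")
    frame = np.asarray(frame)
    fh, fw = frame.shape[:2]
    side = int(np.floor(radius * np.sqrt(2))) - 2 * margin
    if side < 8:
        raise ValueError("margin leaves no usable crop")
    cx, cy = center
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    x1, y1 = x0 + side, y0 + side
    cx0, cy0 = max(0, x0), max(0, y0)
    cx1, cy1 = min(fw, x1), min(fh, y1)
    if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1):
        warnings.warn("inscribed square clipped to frame bounds", stacklevel=2)
    return frame[cy0:cy1, cx0:cx1]


def preprocess_frame(
    frame: np.ndarray,
    working_resolution: int = WORKING_RESOLUTION,
    crop_margin: int = 0,
) -> np.ndarray:
    """Mask-detect, crop the inscribed square, resize to working resolution."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=2)
    mask = detect_circular_mask(frame)
    cropped = crop_inscribed_square(frame, mask.center, mask.radius, margin=crop_margin)
    if cropped.shape != (working_resolution, working_resolution):
        cropped = resize(cropped, (working_resolution, working_resolution), order=1,
                         anti_aliasing=True)
    return cropped


def run_sequence(
    frames: FrameSequence | Sequence[np.ndarray],
    estimator: Estimator,
    cfg: Optional[ConsistencyConfig] = None,
    reference_index: int = 0,
    render: bool = True,
    blend: str = "latest",
    max_canvas_pixels: int = 64_000_000,
) -> SequenceResult:
    """Process a sequence end to end.

    Pairwise homographies come from :func:`consistent_estimate` on each
    adjacent frame pair; a pair whose estimation fails entirely is
    substituted with the identity and logged (never aborts the run).
    Relative homographies are accumulated into the reference plane and,
    optionally, the mosaic is rendered.
    """
    if isinstance(frames, FrameSequence):
        mask = frames.mask
        frame_list = [np.asarray(f, dtype=float) for f in frames.frames]
    else:
        mask = None
        frame_list = [np.asarray(f, dtype=float) for f in frames]
    if len(frame_list) < 2:
        raise ValueError("need at least 2 frames")
    cfg = cfg or ConsistencyConfig()
    pairwise: List[np.ndarray] = []
    failed: List[int] = []
    for k in range(len(frame_list) - 1):
        try:
            h = consistent_estimate(
                frame_list[k], frame_list[k + 1], estimator, cfg, pair_index=k
            )
        except PairEstimationFailure:
            logger.warning("pair (%d, %d): estimation failed; substituting identity", k, k + 1)
            failed.append(k)
            h = np.eye(3)
        pairwise.append(h)
    relative = compose_relative(pairwise, reference_index=reference_index)
    canvas = None
    if render:
        canvas = render_mosaic(
            frame_list, relative, mask=mask, blend=blend, max_canvas_pixels=max_canvas_pixels
        )
    return SequenceResult(pairwise=pairwise, relative=relative, canvas=canvas,
                          failed_pairs=failed)


def render_mosaic(
    frames: Sequence[np.ndarray],
    relative: Sequence[np.ndarray],
    mask=None,
    blend: str = "latest",
    max_canvas_pixels: int = 64_000_000,
) -> MosaicCanvas:
    """Warp every frame into the mosaic plane and blend.

    The canvas is the bounding box of all projected frame corners.
    Each frame is inverse-warped (bilinear) onto the canvas; pixels
    outside the circular mask, when one is given as ``((cx, cy), r)``,
    are excluded.  ``blend`` is ``"latest"`` (later frames on top, the
    layered look of sequential mosaics) or ``"average"`` (feathered
    mean over coverage).
    """
    if len(frames) != len(relative):
        raise ValueError("need exactly one relative homography per frame")
    if blend not in ("latest", "average"):
        raise ValueError("blend must be 'latest' or 'average'")
    relative = [normalize_homography(h) for h in relative]
    all_corners = []
    for frame, h in zip(frames, relative):
        fh, fw = frame.shape[:2]
        all_corners.append(apply_homography(h, default_corners(fw, fh)))
    pts = np.vstack(all_corners)
    min_x, min_y = np.floor(pts.min(axis=0)).astype(int)
    max_x, max_y = np.ceil(pts.max(axis=0)).astype(int)
    cw, ch = max_x - min_x + 1, max_y - min_y + 1
    if cw * ch > max_canvas_pixels:
        raise ValueError(
            f"mosaic canvas {cw}x{ch} exceeds the {max_canvas_pixels}-pixel budget; "
            "downscale the frames or raise max_canvas_pixels"
        )
    image = np.zeros((ch, cw))
    acc = np.zeros((ch, cw))
    coverage = np.zeros((ch, cw), dtype=int)
    offset = translation_matrix(-min_x, -min_y)

    mask_grid = None
    if mask is not None:
        (mcx, mcy), mr = mask
    for frame, h in zip(frames, relative):
        fh, fw = frame.shape[:2]
        m = offset @ h  # frame -> canvas
        m_inv = np.linalg.inv(m)
        # restrict work to this frame's projected bounding box on the canvas
        proj = apply_homography(m, default_corners(fw, fh))
        x0 = max(0, int(np.floor(proj[:, 0].min())))
        y0 = max(0, int(np.floor(proj[:, 1].min())))
        x1 = min(cw - 1, int(np.ceil(proj[:, 0].max())))
        y1 = min(ch - 1, int(np.ceil(proj[:, 1].max())))
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(
            np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float)
        )
        denom = m_inv[2, 0] * gx + m_inv[2, 1] * gy + m_inv[2, 2]
        sx = (m_inv[0, 0] * gx + m_inv[0, 1] * gy + m_inv[0, 2]) / denom
        sy = (m_inv[1, 0] * gx + m_inv[1, 1] * gy + m_inv[1, 2]) / denom
        valid = (sx >= 0) & (sx <= fw - 1) & (sy >= 0) & (sy <= fh - 1)
        if mask is not None:
            valid &= (sx - mcx) ** 2 + (sy - mcy) ** 2 <= mr**2
        if not valid.any():
            continue
        warped = map_coordinates(frame, [sy, sx], order=1, mode="constant", cval=0.0)
        sub_img = image[y0 : y1 + 1, x0 : x1 + 1]
        sub_cov = coverage[y0 : y1 + 1, x0 : x1 + 1]
        if blend == "latest":
            sub_img[valid] = warped[valid]
        else:
            acc[y0 : y1 + 1, x0 : x1 + 1][valid] += warped[valid]
        sub_cov[valid] += 1
    if blend == "average":
        nz = coverage > 0
        image[nz] = acc[nz] / coverage[nz]
    return MosaicCanvas(
        image=image,
        coverage=coverage,
        origin_offset=(float(-min_x), float(-min_y)),
        working_resolution=frames[0].shape[0],
    )
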