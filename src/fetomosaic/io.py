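"""Serialization: homography trajectories as JSON, sequences as PNG directories.

Trajectory JSON schema — a list of records, one per frame::

    {"frame_index": k,
     "h":       [9 floats, row-major 3x3],
     "fourpt":  [8 floats, (du1, dv1, ..., du4, dv4)],
     "corners": [8 floats, (u1, v1, ..., u4, v4)]}

Sequence directories contain zero-padded numbered PNG frames
(``frame_0000.png`` ...), a ``sequence.json`` describing the trajectory
and optional circular mask, and optionally ``gt_pairwise.json`` in the
trajectory schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .homography import FourPointHomography, matrix_to_fourpt, normalize_homography

__all__ = [
    "trajectory_to_records",
    "records_to_matrices",
    "save_trajectory",
    "load_trajectory",
    "save_sequence",
    "save_patch_pairs",
    "load_patch_pairs",
    "load_sequence",
    "frame_to_uint8",
    "frame_to_float",
]


def frame_to_uint8(frame: np.ndarray) -> np.ndarray:
    """Convert a [0, 1] float frame to uint8 for PNG output."""
    return np.clip(np.round(np.asarray(frame, dtype=float) * 255.0), 0, 255).astype(np.uint8)


def frame_to_float(img: np.ndarray) -> np.ndarray:
    """Convert a loaded 8/16-bit image (possibly RGB) to [0, 1] grayscale float."""
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def trajectory_to_records(matrices, corners) -> list:
    corners = np.asarray(corners, dtype=float)
    records = []
    for k, h in enumerate(matrices):
        h = normalize_homography(h)
        fp = matrix_to_fourpt(h, corners)
        records.append(
            {
                "frame_index": k,
                "h": [float(x) for x in h.reshape(-1)],
                "fourpt": [float(x) for x in fp.to_flat()],
                "corners": [float(x) for x in corners.reshape(-1)],
            }
        )
    return records


def records_to_matrices(records) -> list:
    return [normalize_homography(np.asarray(r["h"], dtype=float).reshape(3, 3)) for r in records]


def save_trajectory(path, matrices, corners) -> None:
    Path(path).write_text(json.dumps(trajectory_to_records(matrices, corners), indent=1))


def load_trajectory(path) -> list:
    return records_to_matrices(json.loads(Path(path).read_text()))


def save_sequence(seq, out_dir) -> Path:
    """Write a FrameSequence as numbered PNGs + sequence.json (+ gt_pairwise.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{k:04d}.png", frame_to_uint8(frame))
    meta = {
        "n_frames": len(seq.frames),
        "working_resolution": int(seq.working_resolution),
        "mask": None
        if seq.mask is None
        else {"center": [float(seq.mask[0][0]), float(seq.mask[0][1])], "radius": float(seq.mask[1])},
        "spec": None if seq.spec is None else seq.spec.to_dict(),
    }
    (out / "sequence.json").write_text(json.dumps(meta, indent=1))
    if seq.gt_pairwise is not None:
        size = seq.frames[0].shape
        from .homography import default_corners

        save_trajectory(out / "gt_pairwise.json", seq.gt_pairwise, default_corners(size[1], size[0]))
    return out


def save_patch_pairs(pairs, out_dir) -> Path:
    """Write patch pairs as paired PNGs + a JSON manifest with ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, pair in enumerate(pairs):
        name_a, name_b = f"pair_{k:05d}_a.png", f"pair_{k:05d}_b.png"
        iio.imwrite(out / name_a, frame_to_uint8(pair.patch_a))
        iio.imwrite(out / name_b, frame_to_uint8(pair.patch_b))
        manifest.append(
            {
                "index": k,
                "patch_a": name_a,
                "patch_b": name_b,
                "fourpt": [float(x) for x in pair.gt.to_flat()],
                "corners": [float(x) for x in pair.gt.corners.reshape(-1)],
                "source_id": pair.source_id,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_patch_pairs(pair_dir) -> list:
    """Load a patch-pair dataset written by :func:`save_patch_pairs`."""
    from .synth import PatchPair

    d = Path(pair_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    pairs = []
    for rec in manifest:
        gt = FourPointHomography.from_flat(
            rec["fourpt"], np.asarray(rec["corners"], dtype=float).reshape(4, 2)
        )
        pairs.append(
            PatchPair(
                patch_a=frame_to_float(iio.imread(d / rec["patch_a"])),
                patch_b=frame_to_float(iio.imread(d / rec["patch_b"])),
                gt=gt,
                source_id=rec.get("source_id", ""),
            )
        )
    return pairs


def load_sequence(seq_dir):
    """Load a sequence directory written by :func:`save_sequence`.

    Also accepts a bare directory of image files (sorted by name) with
    no metadata, in which case mask and ground truth are None.
    """
    from .synth import FrameSequence, TrajectorySpec

    d = Path(seq_dir)
    meta_path = d / "sequence.json"
    exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
    frame_paths = sorted(p for p in d.iterdir() if p.suffix.lower() in exts)
    if not frame_paths:
        raise FileNotFoundError(f"no image frames found in {d}")
    frames = [frame_to_float(iio.imread(p)) for p in frame_paths]
    mask = None
    spec = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("mask"):
            mask = (tuple(meta["mask"]["center"]), float(meta["mask"]["radius"]))
        if meta.get("spec"):
            spec = TrajectorySpec.from_dict(meta["spec"])
    gt = None
    gt_path = d / "gt_pairwise.json"
    if gt_path.exists():
        gt = load_trajectory(gt_path)
    return FrameSequence(
        frames=frames,
        mask=mask,
        gt_pairwise=gt,
        working_resolution=frames[0].shape[0],
        spec=spec,
    )
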